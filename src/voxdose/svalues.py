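"""S-value computation, uncertainty propagation, and comparison metrics.

Internal unit is Gy per decay (Gy Bq^-1 s^-1); helpers convert to the
Gy MBq^-1 s^-1 convention used for sphere self-dose tables (factor 1e6).
The mean organ dose is an unweighted voxel mean, even across mixed-density
masks; a mass-weighted variant is provided but is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import MergedDose, UncertaintyGrid
from .phantom import OrganMask, VoxelPhantom

__all__ = [
    "SValueRecord",
    "SValueTable",
    "ReferenceComparison",
    "mean_organ_dose",
    "mean_organ_dose_mass_weighted",
    "compute_svalue",
    "svalue_uncertainty",
    "build_svalue_table",
    "mass_correct",
    "percent_difference",
    "tumour_relative_change",
    "per_decay_to_per_mbq_s",
    "per_mbq_s_to_per_decay",
]


def per_decay_to_per_mbq_s(s: float) -> float:
    """Gy/decay (Gy Bq^-1 s^-1) -> Gy MBq^-1 s^-1."""
    return s * 1e6


def per_mbq_s_to_per_decay(s: float) -> float:
    return s * 1e-6


def mean_organ_dose(merged: MergedDose, mask: OrganMask) -> float:
    """Unweighted voxel mean dose over the mask: sum_k D_k / v."""
    if mask.v < 1:
        raise ValueError("empty organ mask")
    flat = merged.dose.reshape(-1)
    if mask.flat_indices.max() >= flat.size:
        raise ValueError("mask indices outside the dose grid")
    return float(flat[mask.flat_indices].sum() / mask.v)


def mean_organ_dose_mass_weighted(
    merged: MergedDose, mask: OrganMask, phantom: VoxelPhantom
) -> float:
    """Mass-weighted alternative (not the reporting default)."""
    if mask.v < 1:
        raise ValueError("empty organ mask")
    rho = phantom.density_grid().reshape(-1)[mask.flat_indices]
    d = merged.dose.reshape(-1)[mask.flat_indices]
    return float((d * rho).sum() / rho.sum())


def compute_svalue(mean_dose: float, n_primaries: float) -> float:
    """S = D-bar / N, in Gy per decay."""
    if n_primaries < 1:
        raise ValueError("n_primaries must be >= 1")
    return mean_dose / n_primaries


def svalue_uncertainty(unc: UncertaintyGrid, mask: OrganMask, n_primaries: float) -> float:
    """delta S = sqrt( sum_k delta D_k^2 ) / (N v)."""
    if mask.v < 1:
        raise ValueError("empty organ mask")
    d = unc.delta.reshape(-1)[mask.flat_indices]
    return float(np.sqrt(np.sum(d * d)) / (n_primaries * mask.v))


@dataclass(frozen=True)
class SValueRecord:
    source: str
    target: str
    s: float  # Gy per decay
    delta_s: float  # Gy per decay
    n_primaries: float

    def __post_init__(self):
        if self.s < 0 or self.delta_s < 0:
            raise ValueError("S and delta S must be non-negative")

    @property
    def rel_unc_pct(self) -> float:
        return 100.0 * self.delta_s / self.s if self.s > 0 else float("nan")


@dataclass
class SValueTable:
    """S-value records keyed (source, target), plus run metadata."""

    records: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def add(self, rec: SValueRecord) -> None:
        key = (rec.source, rec.target)
        if key in self.records:
            raise ValueError(f"duplicate record for {key}")
        self.records[key] = rec

    def get(self, source: str, target: str) -> SValueRecord:
        return self.records[(source, target)]

    @property
    def sources(self) -> list:
        return sorted({s for s, _ in self.records})

    def to_long_frame(self, units: str = "per-decay") -> pd.DataFrame:
        scale = 1.0 if units == "per-decay" else 1e6
        rows = [
            {
                "source": r.source,
                "target": r.target,
                "S": r.s * scale,
                "dS": r.delta_s * scale,
                "rel_unc_pct": r.rel_unc_pct,
            }
            for r in self.records.values()
        ]
        return pd.DataFrame(rows).sort_values(["source", "target"]).reset_index(drop=True)

    def to_wide_frame(self, units: str = "per-decay") -> pd.DataFrame:
        """Source rows x target columns, '<S> (<rel unc %>)' formatted with
        3 significant figures, mirroring published table style."""
        scale = 1.0 if units == "per-decay" else 1e6

        def fmt(r: SValueRecord) -> str:
            return f"{r.s * scale:.3g} ({r.delta_s * scale:.3g})"

        targets = sorted({t for _, t in self.records})
        data = {
            t: [
                fmt(self.records[(s, t)]) if (s, t) in self.records else ""
                for s in self.sources
            ]
            for t in targets
        }
        return pd.DataFrame(data, index=pd.Index(self.sources, name="source"))


def build_svalue_table(
    merged_by_source: dict,
    unc_by_source: dict,
    masks: dict,
    n_by_source: dict,
    aggregates: dict | None = None,
    metadata: dict | None = None,
) -> SValueTable:
    """One record per (source, target) over all masks, plus aggregate
    union targets (e.g. bone-marrow and whole-skeleton unions).

    `n_by_source` carries the per-realization primaries count N used in
    S = D-bar/N (for equal-size batches, total primaries / batch count).
    """
    table = SValueTable(metadata=dict(metadata or {}))
    missing = [s for s in merged_by_source if s not in n_by_source]
    if missing:
        raise ValueError(f"missing primaries counts for sources {missing}")
    targets = dict(masks)
    for name, mask in (aggregates or {}).items():
        targets[name] = mask
    for source, merged in merged_by_source.items():
        if source not in unc_by_source:
            raise ValueError(f"missing uncertainty grid for source {source!r}")
        unc = unc_by_source[source]
        n = n_by_source[source]
        for target, mask in targets.items():
            s = compute_svalue(mean_organ_dose(merged, mask), n)
            ds = svalue_uncertainty(unc, mask, n)
            table.add(SValueRecord(source=source, target=target, s=s, delta_s=ds,
                                   n_primaries=n))
    return table


@dataclass(frozen=True)
class ReferenceComparison:
    source: str
    target: str
    s_computed: float
    m_phantom_g: float
    m_reference_g: float
    s_reference: float
    s_corrected: float
    pct_difference: float


def mass_correct(s_computed: float, m_phantom_g: float, m_reference_g: float) -> float:
    """Scale an S-value to a reference phantom's organ mass:
    S_corrected = S_computed * (m_phantom / m_reference)."""
    if m_phantom_g <= 0 or m_reference_g <= 0:
        raise ValueError("masses must be > 0")
    return s_computed * (m_phantom_g / m_reference_g)


def percent_difference(a: float, b_reference: float) -> float:
    """100 * (a - b) / b."""
    if b_reference == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (a - b_reference) / b_reference


def tumour_relative_change(s_by_mass: dict, m0: float | None = None) -> dict:
    """Percent change of S relative to the smallest tumour mass:
    100 * (S(m) - S(m0)) / S(m0); exactly 0 at m0."""
    if len(s_by_mass) < 2:
        raise ValueError("need at least two tumour masses")
    if m0 is None:
        m0 = min(s_by_mass)
    s0 = s_by_mass[m0].s if isinstance(s_by_mass[m0], SValueRecord) else s_by_mass[m0]
    if s0 == 0:
        raise ValueError("S at the smallest mass is zero")
    out = {}
    for m, rec in s_by_mass.items():
        s = rec.s if isinstance(rec, SValueRecord) else rec
        out[m] = 0.0 if m == m0 else 100.0 * (s - s0) / s0
    return out
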