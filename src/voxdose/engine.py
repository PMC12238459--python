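"""Simplified voxel dose engine for Lu-177: batches, merging, uncertainty.

The engine transports every emission of each simulated decay through the
phantom grid (straight-line CSDA electrons, analog photoelectric/Compton
photons) and scores per-voxel dose and squared dose, mirroring a dose
actor.  Batches are independent jobs keyed by (master seed, batch index);
merged results are independent of batch ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .lu177 import DecayData, build_spectrum, load_range_table
from .materials import klein_nishina_total, pe_mass_water, photon_energy_grid
from .phantom import ActivityImage, VoxelPhantom

__all__ = [
    "DoseBatch",
    "MergedDose",
    "UncertaintyGrid",
    "EngineScene",
    "run_batch",
    "run_batches",
    "merge_batches",
    "batch_uncertainty",
    "transport_electron",
    "transport_photon",
    "spawn_batch_seeds",
]

KEV_TO_J = 1.602176634e-16


@dataclass(frozen=True)
class DoseBatch:
    """Per-voxel dose (Gy) and squared dose (Gy^2) from one transport run."""

    dose: np.ndarray
    dose_sq: np.ndarray
    n_primaries: int
    seed: int

    def __post_init__(self):
        if self.n_primaries <= 0:
            raise ValueError("n_primaries must be > 0")
        if np.any(self.dose < 0):
            raise ValueError("dose must be non-negative everywhere")
        if self.dose.shape != self.dose_sq.shape:
            raise ValueError("dose and dose_sq shapes differ")


@dataclass(frozen=True)
class MergedDose:
    """Primaries-weighted average dose over batches (equal-n batches: the
    per-batch dose scale); N is the total primaries across batches."""

    dose: np.ndarray
    n_primaries: int
    n_batches: int

    @property
    def primaries_per_batch(self) -> float:
        return self.n_primaries / self.n_batches


@dataclass(frozen=True)
class UncertaintyGrid:
    """delta: statistical dose uncertainty (Gy); rel: delta/D where D>0,
    NaN elsewhere (the undefined flag)."""

    delta: np.ndarray
    rel: np.ndarray


class EngineScene:
    """Prebuilt kernel arrays for one phantom + decay dataset."""

    def __init__(
        self,
        phantom: VoxelPhantom,
        decay_data: DecayData | None = None,
        electron_cut_kev: float = 10.0,
        photon_cut_kev: float = 10.0,
        step_fraction: float = 0.5,
        step_cap_mm: float | None = 0.05,
    ):
        if decay_data is None:
            decay_data = build_spectrum()
        self.phantom = phantom
        self.decay_data = decay_data
        self.electron_cut_kev = float(electron_cut_kev)
        self.photon_cut_kev = float(photon_cut_kev)
        self.h_cm = phantom.voxel_size_mm / 10.0
        # step <= half a voxel; an absolute cap keeps the discretized-escape
        # bias resolution-independent (sub-percent at these energies)
        self.step_cm = step_fraction * self.h_cm
        if step_cap_mm is not None:
            self.step_cm = min(self.step_cm, step_cap_mm / 10.0)
        nx, ny, nz = phantom.shape
        self.shape = (nx, ny, nz)

        # material tables, one slot per label (slot 0 = air)
        labels = sorted(phantom.label_table)
        mats = [None] + [phantom.label_table[l].material for l in labels]
        from .materials import builtin_materials

        mats[0] = builtin_materials()["air"]
        label_to_slot = {0: 0, **{l: i + 1 for i, l in enumerate(labels)}}
        lut = np.zeros(max(labels, default=0) + 1, dtype=np.int32)
        for lab, slot in label_to_slot.items():
            lut[lab] = slot
        self.mat = np.ascontiguousarray(lut[phantom.label_grid].reshape(-1))
        rho_by_slot = np.array([m.density for m in mats])
        sps_by_slot = np.array([m.stopping_power_scale for m in mats])
        self.rho = rho_by_slot[self.mat]
        self.spsc = sps_by_slot[self.mat]
        self.pe_scale = np.array([m.pe_scale for m in mats])
        self.epg = np.array([m.electrons_per_gram for m in mats])

        # photon energy tables
        eg = photon_energy_grid(64)
        self.eg_log = np.log(eg)
        self.pe_log = np.log(pe_mass_water(eg))
        self.kn_log = np.log(klein_nishina_total(eg) * 1e-24)
        mumax = np.zeros_like(eg)
        for m in set(self.mat.tolist()):
            mu = rho_by_slot[m] * (
                pe_mass_water(eg) * self.pe_scale[m]
                + klein_nishina_total(eg) * 1e-24 * self.epg[m]
            )
            mumax = np.maximum(mumax, mu)
        self.mumax_log = np.log(mumax)

        # electron range-energy tables
        tab = load_range_table()
        self.re_loge = np.log(tab.energy_kev)
        self.re_logr = np.log(tab.csda_g_cm2)

        # emission tables
        if decay_data.spectrum is not None and decay_data.beta_branches:
            self.beta_icdf = decay_data.spectrum.inverse_cdf_table(4096)
            self.has_beta = True
        else:
            self.beta_icdf = np.zeros(2)
            self.has_beta = False
        discrete = decay_data.discrete_electrons + decay_data.photons
        self.line_e = np.array([l.energy_kev for l in discrete], dtype=np.float64)
        self.line_yield = np.array([l.yield_per_decay for l in discrete])
        self.line_is_electron = np.array(
            [l.is_electron for l in discrete], dtype=np.uint8
        )
        # voxel mass in kg, per voxel
        self.voxel_mass_kg = self.rho * self.h_cm**3 * 1e-3


def _source_tables(scene: EngineScene, activity: ActivityImage):
    flat = activity.grid.reshape(-1)
    if abs(flat.sum() - 1.0) > 1e-9:
        raise ValueError("activity image is not normalized")
    idx = np.flatnonzero(flat)
    cdf = np.cumsum(flat[idx])
    cdf[-1] = 1.0
    return idx.astype(np.int64), cdf


def run_batch(
    phantom: VoxelPhantom,
    activity: ActivityImage,
    n_primaries: int,
    seed: int,
    scene: EngineScene | None = None,
    decay_data: DecayData | None = None,
) -> DoseBatch:
    """Simulate `n_primaries` decays; deterministic for a (seed, n) pair."""
    if n_primaries < 1:
        raise ValueError("n_primaries must be >= 1")
    if scene is None:
        scene = EngineScene(phantom, decay_data)
    if activity.grid.shape != phantom.shape:
        raise ValueError("activity image shape does not match the phantom")
    src_flat, src_cdf = _source_tables(scene, activity)
    nx, ny, nz = scene.shape
    edep, edep_sq = _kernels.simulate_batch(
        np.uint32(seed & 0xFFFFFFFF), n_primaries,
        nx, ny, nz, scene.h_cm,
        scene.rho, scene.mat, scene.spsc,
        src_flat, src_cdf,
        scene.beta_icdf, scene.has_beta,
        scene.line_e, scene.line_yield, scene.line_is_electron,
        scene.re_loge, scene.re_logr,
        scene.eg_log, scene.pe_log, scene.pe_scale, scene.kn_log,
        scene.epg, scene.mumax_log,
        scene.electron_cut_kev, scene.photon_cut_kev, scene.step_cm,
    )
    conv = KEV_TO_J / scene.voxel_mass_kg  # Gy per keV, per voxel
    dose = (edep * conv).reshape(scene.shape)
    dose_sq = (edep_sq * conv**2).reshape(scene.shape)
    return DoseBatch(dose=dose, dose_sq=dose_sq, n_primaries=n_primaries, seed=seed)


def spawn_batch_seeds(master_seed: int, n_batches: int) -> list[int]:
    """Per-batch child seeds derived from a master seed (documented scheme:
    numpy SeedSequence spawning, first state word of each child)."""
    ss = np.random.SeedSequence(master_seed)
    return [int(c.generate_state(1)[0]) for c in ss.spawn(n_batches)]


def run_batches(
    phantom: VoxelPhantom,
    activity: ActivityImage,
    n_primaries: int,
    n_batches: int,
    master_seed: int,
    scene: EngineScene | None = None,
    decay_data: DecayData | None = None,
) -> list[DoseBatch]:
    """Split `n_primaries` into `n_batches` independent equal batches."""
    if scene is None:
        scene = EngineScene(phantom, decay_data)
    per = n_primaries // n_batches
    if per < 1:
        raise ValueError("fewer primaries than batches")
    seeds = spawn_batch_seeds(master_seed, n_batches)
    return [
        run_batch(phantom, activity, per, s, scene=scene) for s in seeds
    ]


def merge_batches(batches: list[DoseBatch]) -> MergedDose:
    """Primaries-weighted average of batch dose grids:
    D_k = sum_i n_i D_{k,i} / sum_i n_i, with N = sum_i n_i."""
    if not batches:
        raise ValueError("need at least one batch")
    shape = batches[0].dose.shape
    for b in batches:
        if b.dose.shape != shape:
            raise ValueError("batch grid shapes differ")
    n_total = sum(b.n_primaries for b in batches)
    dose = np.zeros(shape, dtype=np.float64)
    # canonical accumulation order -> merged grid independent of batch ordering
    for b in sorted(batches, key=lambda b: (b.seed, b.n_primaries)):
        dose += (b.n_primaries / n_total) * b.dose
    return MergedDose(dose=dose, n_primaries=n_total, n_batches=len(batches))


def batch_uncertainty(batches: list[DoseBatch]) -> UncertaintyGrid:
    """History-by-history-style batch statistics.

    With N batch realizations D_{k,i},
    delta D_k = sqrt( (1/(N-1)) ( sum D^2 / N - (sum D / N)^2 ) ),
    the standard error of the merged (averaged) dose; eps = delta/D where
    the merged dose is positive, NaN elsewhere.
    """
    n = len(batches)
    if n < 2:
        raise ValueError("batch uncertainty needs at least 2 batches")
    shape = batches[0].dose.shape
    s1 = np.zeros(shape)
    s2 = np.zeros(shape)
    for b in batches:
        if b.dose.shape != shape:
            raise ValueError("batch grid shapes differ")
        s1 += b.dose
        s2 += b.dose * b.dose
    var = s2 / n - (s1 / n) ** 2
    delta = np.sqrt(np.clip(var, 0.0, None) / (n - 1))
    mean = s1 / n
    rel = np.full(shape, np.nan)
    pos = mean > 0
    rel[pos] = delta[pos] / mean[pos]
    return UncertaintyGrid(delta=delta, rel=rel)


# -- single-particle interfaces (used by tests and diagnostics) -------------

def transport_electron(
    energy_kev: float,
    position_mm,
    direction,
    phantom: VoxelPhantom,
    deposit: np.ndarray | None = None,
    scene: EngineScene | None = None,
) -> float:
    """Transport one electron; returns total deposited keV.

    `deposit`, if given, is a float64 grid of the phantom shape that
    accumulates per-voxel deposits (keV).
    """
    if energy_kev <= 0:
        raise ValueError("energy must be > 0")
    if scene is None:
        scene = EngineScene(phantom)
    if deposit is None:
        deposit = np.zeros(phantom.shape, dtype=np.float64)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    p = np.asarray(position_mm, dtype=float) / 10.0  # cm
    nx, ny, nz = scene.shape
    return float(
        _kernels.electron_once(
            energy_kev, p[0], p[1], p[2], d[0], d[1], d[2],
            nx, ny, nz, scene.h_cm, scene.rho, scene.spsc,
            scene.re_loge, scene.re_logr,
            scene.electron_cut_kev, scene.step_cm,
            deposit.reshape(-1),
        )
    )


def transport_photon(
    energy_kev: float,
    position_mm,
    direction,
    phantom: VoxelPhantom,
    seed: int = 0,
    deposit: np.ndarray | None = None,
    scene: EngineScene | None = None,
) -> float:
    """Transport one photon (analog MC); returns total deposited keV."""
    if energy_kev <= 0:
        raise ValueError("energy must be > 0")
    if scene is None:
        scene = EngineScene(phantom)
    if deposit is None:
        deposit = np.zeros(phantom.shape, dtype=np.float64)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    p = np.asarray(position_mm, dtype=float) / 10.0
    nx, ny, nz = scene.shape
    return float(
        _kernels.photon_once(
            np.uint32(seed & 0xFFFFFFFF), energy_kev,
            p[0], p[1], p[2], d[0], d[1], d[2],
            nx, ny, nz, scene.h_cm, scene.rho, scene.mat,
            scene.eg_log, scene.pe_log, scene.pe_scale, scene.kn_log,
            scene.epg, scene.mumax_log,
            scene.photon_cut_kev,
            deposit.reshape(-1),
        )
    )
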