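"""Synthetic cohorts with planted, known ground truth.

Everything downstream — voxel statistics, seed functional connectivity (FC),
structural-connectivity (SC) filtering and the SLFC intersection — is tested
against cohorts generated here, because the study design this package
implements (autoradiographic CBF volumes from a 2×2 stress × distension rat
experiment, plus a collated structural connectome) has no public data
deposition to replay.

The generative model per animal volume is deliberately the model the
statistics assume:

    OD(v) = background/brain baseline
          + subgroup effect of the region containing v
          + latent FC component (seed region and coupled regions)
          + i.i.d. Gaussian voxel noise.

The FC component uses one latent standard-normal scalar z per animal: the
seed region receives ``latent_sd · z`` and a region with coupling ρ receives
``latent_sd · (ρ z + √(1−ρ²) z_r)`` with z_r an independent per-region draw,
so the across-animal correlation between seed and region means is ρ in
expectation — planted FC sign and magnitude are analytically known.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .emg import EMGTrace, Epoch
from .errors import ConflictError, SizingError, SpecificationError
from .volume import BrainVolume, DEFAULT_VOXEL_SIZE_UM

#: the four cells of the 2×2 design: treatment × distension pressure (mmHg)
SUBGROUPS: tuple[tuple[str, int], ...] = (
    ("sham", 0), ("sham", 60), ("WAS", 0), ("WAS", 60))

#: default region nomenclature for generated atlases (seed first)
DEFAULT_REGION_NAMES = (
    "PrL", "La", "CeA", "M2", "MPN", "CA1", "PAG", "Cg1", "AI", "VTA",
    "BMA", "LO", "MD", "AHC", "RSG", "DLE")

STRENGTH_CODES = tuple(range(1, 8))
FIBERS_OF_PASSAGE = "fibers_of_passage"


# ---------------------------------------------------------------------------
# label atlas
# ---------------------------------------------------------------------------

@dataclass
class Atlas:
    """Integer label volume plus a (label, name, hemisphere) name table."""

    labels: np.ndarray
    names: pd.DataFrame   # columns: label, name, hemisphere

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        required = {"label", "name", "hemisphere"}
        if not required.issubset(self.names.columns):
            raise ValueError(f"name table needs columns {sorted(required)}")
        if self.names["name"].duplicated().any():
            raise ValueError("region names must be unique")

    @property
    def region_names(self) -> list[str]:
        return list(self.names["name"])

    def label_of(self, name: str) -> int:
        row = self.names[self.names["name"] == name]
        if row.empty:
            raise KeyError(f"unknown region {name!r}")
        return int(row["label"].iloc[0])

    def region_mask(self, name: str) -> np.ndarray:
        return self.labels == self.label_of(name)

    def region_size(self, name: str) -> int:
        return int(self.region_mask(name).sum())

    def save(self, stem: str | Path) -> None:
        from .volume import save_volume
        stem = Path(stem)
        save_volume(BrainVolume(self.labels.astype(float)), stem)
        self.names.to_csv(stem.with_suffix(".tsv"), sep="\t", index=False)


def generate_atlas(grid_shape: Sequence[int], n_regions: int,
                   rng_seed: int = 0,
                   region_names: Sequence[str] | None = None) -> Atlas:
    """Parcellate a grid into ``n_regions`` box-shaped, connected parcels.

    The grid is tiled into cells, cells are shuffled, and each parcel is the
    interior of one cell (a one-voxel background margin keeps parcels
    disjoint and non-touching).  Raises :class:`SizingError` when the grid
    cannot host the requested number of parcels.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if n_regions < 3:
        raise SpecificationError("need at least 3 regions (incl. a seed)")
    if region_names is None:
        base = list(DEFAULT_REGION_NAMES)
        region_names = (base[:n_regions] if n_regions <= len(base) else
                        base + [f"R{i}" for i in range(len(base), n_regions)])
    region_names = list(region_names)
    if len(region_names) != n_regions:
        raise SpecificationError("region_names length must equal n_regions")
    if len(set(region_names)) != n_regions:
        raise SpecificationError("region names must be distinct "
                                 "(hemisphere duplicates need suffixes)")

    # smallest per-axis cell grid whose cells are ≥3 voxels on every axis
    k = [1, 1, 1]
    while k[0] * k[1] * k[2] < n_regions:
        cell = [grid_shape[a] / k[a] for a in range(3)]
        order = np.argsort(cell)[::-1]
        for a in order:
            if grid_shape[a] // (k[a] + 1) >= 3:
                k[a] += 1
                break
        else:
            raise SizingError(
                f"grid {grid_shape} cannot host {n_regions} parcels")

    edges = [np.linspace(0, grid_shape[a], k[a] + 1).astype(int)
             for a in range(3)]
    cells = [tuple((edges[a][i[a]], edges[a][i[a] + 1]) for a in range(3))
             for i in np.ndindex(*k)]
    rng = np.random.default_rng(rng_seed)
    rng.shuffle(cells)

    labels = np.zeros(grid_shape, dtype=int)
    for label, cell in enumerate(cells[:n_regions], start=1):
        sl = []
        for (lo, hi) in cell:
            lo, hi = lo + 1, hi - 1          # margin
            if hi - lo >= 4:                  # jitter where there is room
                lo += int(rng.integers(0, 2))
                hi -= int(rng.integers(0, 2))
            sl.append(slice(lo, hi))
        labels[tuple(sl)] = label
    names = pd.DataFrame({
        "label": np.arange(1, n_regions + 1),
        "name": region_names,
        "hemisphere": "R",
    })
    return Atlas(labels, names)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Parameters of a synthetic 2×2 cohort.

    ``region_effects`` maps region → {(treatment, mmHg): OD offset};
    ``seed_couplings`` maps region → ρ (scalar, all subgroups) or
    region → {treatment: ρ}.  ``noise_sd`` and all offsets are in the same
    arbitrary OD units as ``global_mean``.
    """

    grid_shape: tuple[int, int, int] = (40, 20, 40)
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM
    n_per_subgroup: int = 10
    region_effects: Mapping[str, Mapping[tuple[str, int], float]] = \
        field(default_factory=dict)
    seed_region: str = "PrL"
    seed_couplings: Mapping[str, float | Mapping[str, float]] = \
        field(default_factory=dict)
    latent_sd: float = 1.0
    noise_sd: float = 0.5
    global_mean: float = 100.0
    background_fraction: float = 0.35
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_subgroup < 2:
            raise SpecificationError("n_per_subgroup must be ≥ 2")
        if self.noise_sd <= 0:
            raise SpecificationError("noise_sd must be positive")
        for region, rho in self.seed_couplings.items():
            values = (rho.values() if isinstance(rho, Mapping) else [rho])
            if any(abs(v) > 1 for v in values):
                raise SpecificationError(
                    f"coupling for {region!r} outside [-1, 1]")
        if self.seed_region in self.seed_couplings:
            raise SpecificationError("seed region cannot couple to itself")

    def coupling(self, region: str, treatment: str) -> float:
        rho = self.seed_couplings.get(region, 0.0)
        if isinstance(rho, Mapping):
            return float(rho.get(treatment, 0.0))
        return float(rho)


@dataclass
class GroundTruth:
    """Complete inventory of the structure planted into one cohort."""

    active_regions: dict[str, dict[tuple[str, int], float]]
    fc_regions: dict[str, dict[str, int]]      # region → treatment → ±1
    seed_region: str
    seed_latents: dict[str, float]             # animal id → latent value
    sc_edges: list[tuple[str, str, int]] = field(default_factory=list)


def generate_cohort(spec: CohortSpec, atlas: Atlas
                    ) -> tuple[list[BrainVolume], GroundTruth]:
    """Draw one cohort of 4 × ``n_per_subgroup`` volumes from the spec.

    Background voxels sit at ``background_fraction × global_mean`` so the
    70 %-of-mean intensity mask has something to remove, exactly as film
    background does.
    """
    if atlas.labels.shape != tuple(spec.grid_shape):
        raise SpecificationError(
            f"atlas shape {atlas.labels.shape} != grid {spec.grid_shape}")
    known = set(atlas.region_names)
    for name in list(spec.region_effects) + list(spec.seed_couplings) + \
            [spec.seed_region]:
        if name not in known:
            raise SpecificationError(f"unknown region name {name!r}")

    rng = np.random.default_rng(spec.rng_seed)
    brain = atlas.labels > 0
    base = np.where(brain, spec.global_mean,
                    spec.background_fraction * spec.global_mean)
    has_fc = bool(spec.seed_couplings)
    seed_mask = atlas.region_mask(spec.seed_region)

    volumes: list[BrainVolume] = []
    latents: dict[str, float] = {}
    for treatment, mmhg in SUBGROUPS:
        for i in range(spec.n_per_subgroup):
            animal = f"{treatment}{mmhg}_{i:02d}"
            vol = base.copy()
            for region, offsets in spec.region_effects.items():
                off = float(offsets.get((treatment, mmhg), 0.0))
                if off:
                    vol[atlas.region_mask(region)] += off
            z = float(rng.standard_normal())
            latents[animal] = spec.latent_sd * z
            if has_fc:
                vol[seed_mask] += spec.latent_sd * z
                for region in spec.seed_couplings:
                    rho = spec.coupling(region, treatment)
                    zr = float(rng.standard_normal())
                    vol[atlas.region_mask(region)] += spec.latent_sd * (
                        rho * z + np.sqrt(1.0 - rho ** 2) * zr)
            vol += rng.normal(0.0, spec.noise_sd, size=vol.shape)
            volumes.append(BrainVolume(
                vol, voxel_size_um=spec.voxel_size_um, animal_id=animal,
                treatment=treatment, distension_mmhg=mmhg, normalized=True))

    active = {r: {sg: v for sg, v in offs.items() if v != 0}
              for r, offs in spec.region_effects.items()}
    active = {r: offs for r, offs in active.items() if offs}
    fc = {}
    for region in spec.seed_couplings:
        signs = {t: int(np.sign(spec.coupling(region, t)))
                 for t in ("sham", "WAS") if spec.coupling(region, t) != 0}
        if signs:
            fc[region] = signs
    truth = GroundTruth(active_regions=active, fc_regions=fc,
                        seed_region=spec.seed_region, seed_latents=latents)
    return volumes, truth


# ---------------------------------------------------------------------------
# structural-connectivity table
# ---------------------------------------------------------------------------

def generate_sc_table(region_names: Sequence[str], density: float,
                      rng_seed: int = 0,
                      planted_edges: Sequence[tuple] | None = None,
                      p_fibers: float = 0.05,
                      p_contra: float = 0.15) -> pd.DataFrame:
    """Random directed connectivity reports emulating a collated SC table.

    Every ordered ipsilateral region pair is included independently with
    probability ``density`` and given a strength code drawn uniformly from
    1–7 (1 = very strong … 7 = very weak) or, with probability
    ``p_fibers``, the 'fibers of passage' code.  A fraction of pairs also
    receives a contralateral duplicate row — those exist solely to exercise
    the ipsilateral-only filter.  ``planted_edges`` — tuples
    (source, target, strength[, laterality]) — are always present verbatim;
    contradictory duplicates raise :class:`ConflictError`.
    """
    if not 0 <= density <= 1:
        raise SpecificationError("density must be in (0, 1]")
    rng = np.random.default_rng(rng_seed)
    region_names = list(region_names)

    planted: dict[tuple[str, str, str], int | str] = {}
    for edge in (planted_edges or []):
        source, target, strength = edge[0], edge[1], edge[2]
        laterality = edge[3] if len(edge) > 3 else "ipsi"
        key = (source, target, laterality)
        if key in planted and planted[key] != strength:
            raise ConflictError(
                f"planted edge {source}->{target} ({laterality}) given "
                f"strengths {planted[key]} and {strength}")
        planted[key] = strength

    rows = []
    for source in region_names:
        for target in region_names:
            if source == target:
                continue
            if (source, target, "ipsi") not in planted and \
                    rng.random() < density:
                strength: int | str = int(rng.integers(1, 8))
                if rng.random() < p_fibers:
                    strength = FIBERS_OF_PASSAGE
                rows.append((source, target, strength, "ipsi", "simulated"))
            if rng.random() < density * p_contra:
                rows.append((source, target, int(rng.integers(1, 8)),
                             "contra", "simulated"))
    for (source, target, laterality), strength in planted.items():
        rows.append((source, target, strength, laterality, "planted"))
    return pd.DataFrame(rows, columns=[
        "source", "target", "strength_code", "laterality", "reference_note"])


# ---------------------------------------------------------------------------
# EMG traces
# ---------------------------------------------------------------------------

def generate_emg(duration_s: float, fs: float,
                 epochs: Sequence[tuple], rng_seed: int = 0,
                 baseline_sd: float = 1.0,
                 movement_amplitude: float = 2.0) -> EMGTrace:
    """Synthetic abdominal-EMG record: broadband baseline noise, a slow
    movement artifact (well below the 20-Hz filter corner), and a broadband
    burst of the given amplitude (signal units, additive noise SD) inside
    each distension epoch.

    ``epochs`` are tuples (onset_s, duration_s, amplitude[, pressure, day]).
    """
    if fs < 100:
        raise SpecificationError("fs must be ≥ 100 Hz")
    n = int(round(duration_s * fs))
    parsed = []
    for e in epochs:
        onset, dur, amp = float(e[0]), float(e[1]), float(e[2])
        pressure = e[3] if len(e) > 3 else None
        day = e[4] if len(e) > 4 else None
        if onset < 0 or onset + dur > duration_s:
            raise SpecificationError(f"epoch at {onset}s outside the record")
        parsed.append((onset, dur, amp, pressure, day))
    parsed.sort(key=lambda e: e[0])
    for a, b in zip(parsed, parsed[1:]):
        if a[0] + a[1] > b[0]:
            raise SpecificationError(
                f"epochs at {a[0]}s and {b[0]}s overlap")

    rng = np.random.default_rng(rng_seed)
    t = np.arange(n) / fs
    signal = rng.normal(0.0, baseline_sd, size=n)
    signal += movement_amplitude * baseline_sd * (
        np.sin(2 * np.pi * 1.5 * t) + 0.5 * np.sin(2 * np.pi * 0.4 * t))
    annotations = []
    for onset, dur, amp, pressure, day in parsed:
        i0, i1 = int(round(onset * fs)), int(round((onset + dur) * fs))
        if amp:
            signal[i0:i1] += rng.normal(0.0, amp, size=i1 - i0)
        annotations.append(Epoch(onset_s=onset, duration_s=dur,
                                 pressure_mmhg=pressure, day=day))
    return EMGTrace(samples=signal, fs=fs, epochs=annotations)
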