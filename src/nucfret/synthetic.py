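"""Synthetic data generators with known ground truth.

Every pipeline stage is validated by parameter recovery on data from these
generators:

* photon streams emulating diffusion spFRET of a nucleosome species
  mixture (LF/MF/HF) with shot-noise-limited burst statistics,
* salt-titration tables drawn from the four-parameter logistic with
  replicate noise,
* toy structures/trajectories whose hydrogen bonds, contacts and segment
  center-of-mass distances are scripted and therefore known exactly.

Per-burst proximity-ratio heterogeneity is binomial shot noise convolved
with an optional Gaussian "extra width"; photophysics (blinking,
bleaching) is deliberately omitted.  All generators are reproducible:
the same seed yields identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .bursts import ACCEPTOR, DONOR, PhotonStream
from .mdgeom import StructureModel, Trajectory
from .titration import TitrationPoint, logistic4

__all__ = [
    "FretSpecies",
    "SpeciesMixtureSpec",
    "TitrationTruth",
    "simulate_photon_stream",
    "simulate_titration",
    "TrajectoryScript",
    "make_toy_trajectory",
    "hbond_toy",
    "duplex_toy",
    "random_walk_toy",
]


@dataclass(frozen=True)
class FretSpecies:
    """One FRET species: label, true mean P, extra width, mixture weight."""

    label: str
    true_mean_p: float
    weight: float
    extra_width: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.true_mean_p <= 1.0):
            raise ValidationError("true_mean_p must be in [0, 1]")
        if self.weight < 0 or self.extra_width < 0:
            raise ValidationError("weight and extra_width must be >= 0")


# canonical three-species mixture: open / intact / partially disassembled
DEFAULT_SPECIES = (
    FretSpecies("LF", 0.12, 1 / 3),
    FretSpecies("MF", 0.39, 1 / 3),
    FretSpecies("HF", 0.64, 1 / 3),
)


@dataclass(frozen=True)
class SpeciesMixtureSpec:
    """Burst-level generative model for a diffusion spFRET measurement.

    Burst sizes are uniform on [min, max] photons; intra-burst photon
    gaps are exponential with mean ``intra_gap_mean_us`` (must be well
    below the burst-search gap threshold) and inter-burst gaps
    exponential with mean ``inter_gap_mean_us`` (well above it).
    Background photons are superposed Poisson processes per channel.
    """

    species: tuple[FretSpecies, ...] = DEFAULT_SPECIES
    burst_size_min: int = 50
    burst_size_max: int = 150
    intra_gap_mean_us: float = 10.0
    inter_gap_mean_us: float = 10_000.0
    bkg_rate_donor: float = 0.0
    bkg_rate_acceptor: float = 0.0
    max_gap_us: float = 120.0  # burst-search gap the rates must respect

    def __post_init__(self):
        w = sum(s.weight for s in self.species)
        if abs(w - 1.0) > 1e-9:
            raise ValidationError(f"species weights sum to {w}, not 1")
        if self.burst_size_min < 1 or self.burst_size_max < self.burst_size_min:
            raise ValidationError("invalid burst size range")
        if self.intra_gap_mean_us >= self.max_gap_us:
            raise ValidationError(
                "mean intra-burst gap >= burst-search gap: burst and "
                "background regimes are indistinguishable")
        if self.inter_gap_mean_us <= self.max_gap_us:
            raise ValidationError("mean inter-burst gap must exceed the "
                                  "burst-search gap")


def simulate_photon_stream(spec: SpeciesMixtureSpec, n_bursts: int,
                           seed: int | np.random.Generator = 0,
                           ) -> tuple[PhotonStream, pd.DataFrame]:
    """Simulate a photon stream of ``n_bursts`` bursts plus background.

    Per burst, a species is drawn by weight, a size uniformly from the
    configured range, and a true proximity ratio from
    Normal(species mean, extra width) truncated to [0, 1]; each photon is
    then an acceptor photon with that probability (binomial shot noise).

    Returns the stream and a truth table with one row per burst
    (species, true P, size, start/end time).
    """
    rng = np.random.default_rng(seed)
    species = spec.species
    weights = np.array([s.weight for s in species])
    sp_idx = rng.choice(len(species), size=n_bursts, p=weights)
    sizes = rng.integers(spec.burst_size_min, spec.burst_size_max + 1,
                         size=n_bursts)
    means = np.array([s.true_mean_p for s in species])[sp_idx]
    widths = np.array([s.extra_width for s in species])[sp_idx]
    p_true = means.copy()
    wide = widths > 0
    if wide.any():
        from scipy.stats import truncnorm
        m, w = means[wide], widths[wide]
        p_true[wide] = truncnorm.rvs((0.0 - m) / w, (1.0 - m) / w,
                                     loc=m, scale=w, random_state=rng)

    total_photons = int(sizes.sum())
    # channel draws, burst by burst (p varies per burst)
    chans = np.empty(total_photons, dtype=np.int8)
    offs = np.concatenate(([0], np.cumsum(sizes)))
    u = rng.random(total_photons)
    for i in range(n_bursts):
        lo, hi = offs[i], offs[i + 1]
        chans[lo:hi] = np.where(u[lo:hi] < p_true[i], ACCEPTOR, DONOR)

    # arrival times: exponential intra gaps, exponential inter-burst gaps
    gaps = rng.exponential(spec.intra_gap_mean_us, size=total_photons)
    inter = rng.exponential(spec.inter_gap_mean_us, size=n_bursts)
    gaps[offs[:-1]] = inter  # first photon of each burst starts a new gap
    times = np.cumsum(gaps)

    starts = times[offs[:-1]]
    ends = times[offs[1:] - 1]
    duration = float(times[-1] + spec.inter_gap_mean_us)

    # superpose background photons as Poisson processes
    bkg_t, bkg_c = [], []
    for rate, code in ((spec.bkg_rate_donor, DONOR),
                       (spec.bkg_rate_acceptor, ACCEPTOR)):
        if rate > 0:
            n_bkg = rng.poisson(rate * duration * 1e-6)
            bkg_t.append(rng.uniform(0.0, duration, size=n_bkg))
            bkg_c.append(np.full(n_bkg, code, dtype=np.int8))
    if bkg_t:
        times = np.concatenate([times] + bkg_t)
        chans = np.concatenate([chans] + bkg_c)
        order = np.argsort(times, kind="stable")
        times, chans = times[order], chans[order]

    stream = PhotonStream(times, chans,
                          bkg_rate_donor=spec.bkg_rate_donor,
                          bkg_rate_acceptor=spec.bkg_rate_acceptor,
                          duration_us=duration)
    truth = pd.DataFrame({
        "burst": np.arange(n_bursts),
        "species": [species[i].label for i in sp_idx],
        "p_true": p_true,
        "size": sizes,
        "start_us": starts,
        "end_us": ends,
    })
    return stream, truth


@dataclass(frozen=True)
class TitrationTruth:
    """Ground truth for a simulated salt titration."""

    p0: float = 1.0
    p_inf: float = 0.1
    c_half_mm: float = 800.0
    slope_b: float = 60.0
    noise_sd: float = 0.02
    n_replicates: int = 3
    concentrations_mm: tuple[float, ...] = (
        5, 100, 200, 300, 400, 500, 600, 700, 800, 900, 1000, 1100, 1200)

    def __post_init__(self):
        concs = self.concentrations_mm
        if len(set(concs)) != len(concs) or min(concs) < 0:
            raise ValidationError("concentrations must be distinct and >= 0")
        if self.noise_sd < 0 or self.n_replicates < 1:
            raise ValidationError("invalid noise_sd / n_replicates")


def simulate_titration(truth: TitrationTruth,
                       seed: int | np.random.Generator = 0,
                       ) -> tuple[list[TitrationPoint], pd.DataFrame]:
    """Draw a noisy titration series from the four-parameter logistic.

    Returns the aggregated points (replicate mean/SD per concentration)
    and the replicate-level table.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for c in truth.concentrations_mm:
        p_ideal = logistic4(c, truth.p0, truth.p_inf, truth.c_half_mm,
                            truth.slope_b)
        for rep in range(truth.n_replicates):
            rows.append({"nacl_mm": float(c), "replicate_id": rep,
                         "p": float(p_ideal
                                    + truth.noise_sd * rng.standard_normal())})
    df = pd.DataFrame(rows)
    g = df.groupby("nacl_mm")["p"]
    sds = g.std(ddof=1).fillna(0.0) if truth.n_replicates > 1 else \
        g.std(ddof=0)
    points = [TitrationPoint(float(c), float(m), float(s), int(n))
              for c, m, s, n in zip(g.mean().index, g.mean(), sds, g.count())]
    return points, df


# -- toy trajectories -------------------------------------------------------

#: per-atom tuple: (name, element, mass, res_name, res_id, chain_id)
AtomTuple = tuple[str, str, float, str, int, str]


@dataclass
class TrajectoryScript:
    """Scripted positions for a small toy structure.

    ``positions`` is either an (n_frames, n_atoms, 3) array in nm or a
    callable mapping a time (ps) to an (n_atoms, 3) array.
    """

    atoms: list[AtomTuple]
    times_ps: np.ndarray
    positions: np.ndarray | Callable[[float], np.ndarray]

    def __post_init__(self):
        if len(self.atoms) > 200:
            raise ValidationError("toy structures are limited to 200 atoms")


def make_toy_trajectory(script: TrajectoryScript) -> Trajectory:
    """Materialise a scripted toy trajectory."""
    names, elements, masses, resnames, resids, chains = \
        (np.array(col) for col in zip(*script.atoms))
    structure = StructureModel(atom_names=names, elements=elements,
                               masses=masses.astype(float),
                               res_names=resnames,
                               res_ids=resids.astype(int), chain_ids=chains)
    times = np.asarray(script.times_ps, dtype=float)
    if callable(script.positions):
        coords = np.stack([script.positions(t) for t in times])
    else:
        coords = np.asarray(script.positions, dtype=float)
    return Trajectory(structure=structure, times_ps=times, coords_nm=coords)


def hbond_toy(n_frames: int = 100, bound_fraction: float = 0.37,
              dt_ps: float = 100.0, seed: int = 0,
              ) -> tuple[Trajectory, dict]:
    """Donor/hydrogen + acceptor triad bonded in a known set of frames.

    In "bound" frames the acceptor sits 0.30 nm from the donor along the
    donor-hydrogen axis (distance and angle criteria met); otherwise it is
    moved to 0.90 nm (criteria violated).  Truth records the bound frame
    indices and the occupancy fraction.
    """
    rng = np.random.default_rng(seed)
    n_bound = int(round(bound_fraction * n_frames))
    bound = np.zeros(n_frames, dtype=bool)
    bound[rng.choice(n_frames, size=n_bound, replace=False)] = True

    atoms: list[AtomTuple] = [
        ("N", "N", 14.0, "DON", 1, "X"),
        ("H", "H", 1.0, "DON", 1, "X"),
        ("O", "O", 16.0, "ACC", 2, "Y"),
    ]
    coords = np.zeros((n_frames, 3, 3))
    coords[:, 1] = [0.10, 0.0, 0.0]                # H 0.10 nm from donor
    coords[:, 2] = np.where(bound[:, None],
                            [0.30, 0.0, 0.0],      # along the N-H axis
                            [0.90, 0.0, 0.0])
    times = dt_ps * np.arange(n_frames)
    traj = make_toy_trajectory(TrajectoryScript(atoms, times, coords))
    return traj, {"bound_frames": np.flatnonzero(bound),
                  "occupancy": n_bound / n_frames}


def duplex_toy(n_frames: int = 10, dt_ps: float = 100.0,
               ) -> tuple[Trajectory, dict]:
    """Mock 20-bp duplex with scripted arm-segment COM distances.

    All atoms of a base pair coincide, so each 5-bp window's COM is known
    exactly: windows 1-5 and 16-20 are 4.0 nm apart, windows 6-10 and
    11-15 are 2.0 nm apart, constant over all frames.
    """
    n_bp = 20
    bp_x = np.empty(n_bp)
    bp_x[0:5] = 0.0     # window 1-5
    bp_x[5:10] = 1.0    # window 6-10
    bp_x[10:15] = 3.0   # window 11-15
    bp_x[15:20] = 4.0   # window 16-20
    atoms: list[AtomTuple] = []
    pos = []
    for i in range(n_bp):  # strand 1: residues 1..20, 5'->3'
        atoms.append(("C1'", "C", 12.0, "DA", i + 1, "I"))
        pos.append([bp_x[i], 0.0, 0.0])
    for i in range(n_bp):  # strand 2: residue j pairs bp n_bp+1-j
        atoms.append(("C1'", "C", 12.0, "DT", i + 1, "J"))
        pos.append([bp_x[n_bp - 1 - i], 0.0, 0.0])
    coords = np.tile(np.array(pos), (n_frames, 1, 1))
    times = dt_ps * np.arange(n_frames)
    traj = make_toy_trajectory(TrajectoryScript(atoms, times, coords))
    truth = {"1-5bp": 4.0, "6-10bp": 2.0, "11-15bp": 2.0, "16-20bp": 4.0}
    return traj, truth


def random_walk_toy(n_atoms: int = 20, n_frames: int = 50,
                    step_nm: float = 0.15, box_nm: float = 2.0,
                    seed: int = 0) -> Trajectory:
    """Atoms random-walking in a cube; for brute-force oracle comparisons."""
    rng = np.random.default_rng(seed)
    atoms: list[AtomTuple] = [
        (f"C{i}", "C", 12.0, "TOY", i + 1, "A" if i < n_atoms // 2 else "B")
        for i in range(n_atoms)]
    start = rng.uniform(0, box_nm, size=(n_atoms, 3))
    steps = rng.normal(0, step_nm, size=(n_frames - 1, n_atoms, 3))
    coords = np.concatenate(([start], start + np.cumsum(steps, axis=0)))
    times = 100.0 * np.arange(n_frames)
    return make_toy_trajectory(TrajectoryScript(atoms, times, coords))
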