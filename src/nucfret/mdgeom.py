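"""Trajectory geometry operators: H-bonds, contacts, DNA-arm distances.

These operators quantify, on all-atom nucleosome trajectories, the
structural signals used to interpret the FRET results:

* hydrogen-bond occupancy between residue pairs over an analysis window
  (default 20-150 ns), with the conventional geometric criterion
  (donor-acceptor heavy-atom distance <= 0.35 nm and
  hydrogen-donor-acceptor angle <= 30 deg);
* heavy-atom contact counts between atom groups (distance strictly
  below 0.35 nm);
* per-frame distances between the centers of mass of 5-bp DNA-arm
  segments and their counterparts on the opposite arm, with a 200-ps
  trailing running average for plotting.

Coordinates are in nm and times in ps throughout.  Trajectories are
assumed whole/unwrapped; an orthorhombic periodic box can be supplied for
minimum-image distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import ValidationError

__all__ = [
    "StructureModel",
    "Trajectory",
    "AtomSelection",
    "SegmentPairSpec",
    "DistanceSeries",
    "hbond_occupancy",
    "count_contacts",
    "arm_segment_distances",
    "running_average",
    "contact_probability",
]

HBOND_DIST_NM = 0.35
HBOND_ANGLE_DEG = 30.0
CONTACT_DIST_NM = 0.35
COVALENT_H_NM = 0.12  # geometric H-to-donor bonding cutoff


@dataclass
class StructureModel:
    """Static topology: parallel per-atom arrays.

    Chains identify histone copies and the two DNA strands; residue
    indices must be unique within a chain.
    """

    atom_names: np.ndarray
    elements: np.ndarray
    masses: np.ndarray
    res_names: np.ndarray
    res_ids: np.ndarray
    chain_ids: np.ndarray

    def __post_init__(self):
        arrs = [np.asarray(a) for a in
                (self.atom_names, self.elements, self.masses,
                 self.res_names, self.res_ids, self.chain_ids)]
        (self.atom_names, self.elements, self.masses,
         self.res_names, self.res_ids, self.chain_ids) = arrs
        n = len(self.atom_names)
        if any(len(a) != n for a in arrs):
            raise ValidationError("per-atom arrays differ in length")
        self.masses = self.masses.astype(float)
        if np.any(self.masses <= 0):
            raise ValidationError("atom masses must be > 0")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def is_heavy(self) -> np.ndarray:
        return np.char.upper(self.elements.astype(str)) != "H"

    def residues_of_chain(self, chain_id: str) -> np.ndarray:
        """Residue ids of a chain, in 5'->3' (ascending resid) order."""
        mask = self.chain_ids == chain_id
        if not mask.any():
            raise ValidationError(f"chain {chain_id!r} not found")
        return np.unique(self.res_ids[mask])


@dataclass
class Trajectory:
    """Frames of timestamped coordinates (nm) over a StructureModel."""

    structure: StructureModel
    times_ps: np.ndarray
    coords_nm: np.ndarray  # (n_frames, n_atoms, 3)
    box_nm: np.ndarray | None = None  # orthorhombic box lengths, optional

    def __post_init__(self):
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        self.coords_nm = np.asarray(self.coords_nm, dtype=float)
        if self.coords_nm.ndim != 3 or \
                self.coords_nm.shape[1] != self.structure.n_atoms:
            raise ValidationError("coords must be (n_frames, n_atoms, 3)")
        if len(self.times_ps) != self.coords_nm.shape[0]:
            raise ValidationError("times and frames differ in length")
        if len(self.times_ps) > 1 and np.any(np.diff(self.times_ps) <= 0):
            raise ValidationError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times_ps)

    def window(self, t_start_ps: float, t_end_ps: float) -> np.ndarray:
        """Frame indices with t_start <= t <= t_end (endpoints inclusive)."""
        if t_start_ps < self.times_ps[0] or t_end_ps > self.times_ps[-1]:
            raise ValidationError(
                f"window [{t_start_ps}, {t_end_ps}] ps outside trajectory "
                f"span [{self.times_ps[0]}, {self.times_ps[-1]}] ps")
        return np.flatnonzero((self.times_ps >= t_start_ps)
                              & (self.times_ps <= t_end_ps))

    @classmethod
    def from_pdb(cls, path, frame_dt_ps: float = 1.0) -> "Trajectory":
        """Load a (multi-model) PDB file; coordinates converted A -> nm.

        Frame times are taken as ``frame_dt_ps`` times the model index
        (PDB files carry no time stamps).
        """
        import MDAnalysis as mda
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
            atoms = u.atoms
            try:
                elements = atoms.elements.astype(str)
            except Exception:
                elements = np.array([mda.topology.guessers.guess_atom_element(n)
                                     for n in atoms.names])
            try:
                masses = atoms.masses.astype(float)
            except Exception:
                masses = np.ones(len(atoms))
            if np.any(masses <= 0):
                masses = np.where(masses <= 0, 1.0, masses)
            try:
                chains = atoms.chainIDs.astype(str)
            except Exception:
                chains = atoms.segids.astype(str)
            structure = StructureModel(
                atom_names=atoms.names.astype(str),
                elements=elements,
                masses=masses,
                res_names=atoms.resnames.astype(str),
                res_ids=atoms.resids.astype(int),
                chain_ids=chains,
            )
            coords = np.array([atoms.positions / 10.0
                               for _ in u.trajectory])
        times = frame_dt_ps * np.arange(coords.shape[0])
        return cls(structure=structure, times_ps=times, coords_nm=coords)


@dataclass(frozen=True)
class AtomSelection:
    """Deterministic atom predicate: chains, resid ranges, names, heaviness.

    ``parse`` accepts a small grammar of "and"-joined terms, e.g.
    ``"chain C and resid 81 and heavy"`` or ``"resid 10:20 and name P"``.
    """

    chains: tuple[str, ...] | None = None
    res_ids: tuple[int, ...] | None = None
    names: tuple[str, ...] | None = None
    res_names: tuple[str, ...] | None = None
    heavy_only: bool = False

    @classmethod
    def parse(cls, text: str) -> "AtomSelection":
        chains = res_ids = names = res_names = None
        heavy = False
        for term in (t.strip() for t in text.split(" and ")):
            parts = term.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("heavy", "noh"):
                heavy = True
            elif key == "chain":
                chains = tuple(parts[1:])
            elif key == "resid":
                ids: list[int] = []
                for tok in parts[1:]:
                    if ":" in tok or "-" in tok:
                        sep = ":" if ":" in tok else "-"
                        lo, hi = tok.split(sep)
                        ids.extend(range(int(lo), int(hi) + 1))
                    else:
                        ids.append(int(tok))
                res_ids = tuple(ids)
            elif key == "name":
                names = tuple(parts[1:])
            elif key == "resname":
                res_names = tuple(parts[1:])
            else:
                raise ValidationError(f"unknown selection term {term!r}")
        return cls(chains=chains, res_ids=res_ids, names=names,
                   res_names=res_names, heavy_only=heavy)

    def indices(self, s: StructureModel) -> np.ndarray:
        """Order-stable atom index list on a structure."""
        mask = np.ones(s.n_atoms, dtype=bool)
        if self.chains is not None:
            mask &= np.isin(s.chain_ids, self.chains)
        if self.res_ids is not None:
            mask &= np.isin(s.res_ids, self.res_ids)
        if self.names is not None:
            mask &= np.isin(s.atom_names, self.names)
        if self.res_names is not None:
            mask &= np.isin(s.res_names, self.res_names)
        if self.heavy_only:
            mask &= s.is_heavy
        return np.flatnonzero(mask)


@dataclass(frozen=True)
class SegmentPairSpec:
    """DNA arm-end 5-bp windows paired across the two arms.

    Windows are 1-based base-pair positions counted from each DNA terminus
    inward; bp i pairs residue i (5'->3') of strand 1 with residue
    N+1-i of strand 2.
    """

    strand1_chain: str = "I"
    strand2_chain: str = "J"
    windows: tuple[tuple[int, int], ...] = ((1, 5), (6, 10), (11, 15), (16, 20))

    def __post_init__(self):
        spans = sorted(self.windows)
        for (a, b), (c, d) in zip(spans, spans[1:]):
            if c <= b:
                raise ValidationError("bp windows must be disjoint")


@dataclass
class DistanceSeries:
    """A labeled per-frame distance time series (ps, nm)."""

    times_ps: np.ndarray
    values: np.ndarray
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.times_ps, "value": self.values,
                             "label": self.label})


def _pair_dists(a: np.ndarray, b: np.ndarray,
                box_nm: np.ndarray | None = None) -> np.ndarray:
    """All pairwise distances between coordinate sets (minimum image when
    a box is given)."""
    diff = a[:, None, :] - b[None, :, :]
    if box_nm is not None:
        box = np.asarray(box_nm, dtype=float)
        diff -= box * np.round(diff / box)
    return np.sqrt((diff ** 2).sum(axis=-1))


def hbond_occupancy(traj: Trajectory, donors: AtomSelection,
                    acceptors: AtomSelection,
                    d_cut_nm: float = HBOND_DIST_NM,
                    angle_cut_deg: float = HBOND_ANGLE_DEG,
                    t_start_ps: float = 20000.0,
                    t_end_ps: float = 150000.0) -> pd.DataFrame:
    """Hydrogen-bond occupancy per donor-acceptor residue pair.

    A hydrogen bond exists in a frame when a donor heavy atom D and an
    acceptor heavy atom A satisfy |DA| <= ``d_cut_nm`` and some hydrogen H
    covalently bound to D (same residue, |DH| < 0.12 nm) makes an H-D-A
    angle <= ``angle_cut_deg``.  Occupancy is the fraction of frames in
    the inclusive [t_start, t_end] window in which any qualifying bond
    exists for the residue pair.

    Returns a DataFrame with columns donor_chain, donor_resid,
    acceptor_chain, acceptor_resid, occupancy.
    """
    s = traj.structure
    d_idx = donors.indices(s)
    a_idx = acceptors.indices(s)
    d_idx = d_idx[s.is_heavy[d_idx]]
    a_idx = a_idx[s.is_heavy[a_idx]]
    if d_idx.size == 0:
        raise ValidationError("donor selection resolves to no heavy atoms")
    if a_idx.size == 0:
        raise ValidationError("acceptor selection resolves to no heavy atoms")
    frames = traj.window(t_start_ps, t_end_ps)

    h_idx = np.flatnonzero(~s.is_heavy)
    cos_cut = np.cos(np.deg2rad(angle_cut_deg))

    # residue-pair keys
    def res_key(i):
        return (str(s.chain_ids[i]), int(s.res_ids[i]))

    pair_hits: dict[tuple, int] = {}
    pair_keys = {(res_key(di), res_key(ai))
                 for di in d_idx for ai in a_idx
                 if res_key(di) != res_key(ai)}
    for key in pair_keys:
        pair_hits[key] = 0

    for fi in frames:
        xyz = traj.coords_nm[fi]
        dmat = _pair_dists(xyz[d_idx], xyz[a_idx], traj.box_nm)
        close = np.argwhere(dmat <= d_cut_nm)
        hit_pairs = set()
        for r, c in close:
            di, ai = d_idx[r], a_idx[c]
            key = (res_key(di), res_key(ai))
            if key not in pair_hits or key in hit_pairs:
                continue
            # hydrogens covalently bound to this donor (same residue)
            same_res = h_idx[(s.chain_ids[h_idx] == s.chain_ids[di])
                             & (s.res_ids[h_idx] == s.res_ids[di])]
            if same_res.size == 0:
                continue
            dh = np.linalg.norm(xyz[same_res] - xyz[di], axis=1)
            hs = same_res[dh < COVALENT_H_NM]
            if hs.size == 0:
                continue
            v_da = xyz[ai] - xyz[di]
            v_dh = xyz[hs] - xyz[di]
            cosang = (v_dh @ v_da) / (
                np.linalg.norm(v_dh, axis=1) * np.linalg.norm(v_da) + 1e-30)
            if np.any(cosang >= cos_cut):
                hit_pairs.add(key)
        for key in hit_pairs:
            pair_hits[key] += 1

    nf = len(frames)
    rows = [{"donor_chain": dk[0], "donor_resid": dk[1],
             "acceptor_chain": ak[0], "acceptor_resid": ak[1],
             "occupancy": hits / nf}
            for (dk, ak), hits in sorted(pair_hits.items())]
    return pd.DataFrame(rows)


def count_contacts(traj: Trajectory, group_a: AtomSelection,
                   group_b: AtomSelection,
                   d_cut_nm: float = CONTACT_DIST_NM) -> np.ndarray:
    """Per-frame number of heavy-atom pairs closer than ``d_cut_nm``.

    Hydrogens are excluded automatically; the inequality is strict
    (a pair at exactly the cutoff does not count).  Pairs consisting of
    the same atom (overlapping selections) are excluded with a warning.
    """
    s = traj.structure
    ia = group_a.indices(s)
    ib = group_b.indices(s)
    ia = ia[s.is_heavy[ia]]
    ib = ib[s.is_heavy[ib]]
    if ia.size == 0 or ib.size == 0:
        return np.zeros(traj.n_frames, dtype=int)
    overlap = np.isin(ia, ib).any()
    if overlap:
        warnings.warn("selections overlap; identical-atom pairs excluded")
    counts = np.empty(traj.n_frames, dtype=int)
    same = ia[:, None] == ib[None, :]
    for fi in range(traj.n_frames):
        xyz = traj.coords_nm[fi]
        d = _pair_dists(xyz[ia], xyz[ib], traj.box_nm)
        hit = d < d_cut_nm
        if overlap:
            hit &= ~same
        counts[fi] = int(hit.sum())
    return counts


def arm_segment_distances(traj: Trajectory,
                          spec: SegmentPairSpec = SegmentPairSpec(),
                          heavy_only: bool = False) -> dict[str, DistanceSeries]:
    """COM distance between each arm-end DNA segment and its counterpart.

    For each bp window (e.g. 1-5), the segment on one arm comprises all
    atoms of both strands' residues for bp 1-5 counted from the 5' end of
    strand 1; its counterpart comprises the same window counted from the
    opposite terminus.  Per frame, the Euclidean distance between the two
    mass-weighted centers is returned.  All atoms enter the COM by
    default; ``heavy_only`` restricts to non-hydrogens.
    """
    s = traj.structure
    res1 = s.residues_of_chain(spec.strand1_chain)
    res2 = s.residues_of_chain(spec.strand2_chain)
    n_bp = len(res1)
    if len(res2) != n_bp:
        raise ValidationError(
            f"strands differ in length: {n_bp} vs {len(res2)}")

    def bp_atoms(bp: int) -> np.ndarray:
        """Atom indices of base pair bp (1-based from strand-1 5' end)."""
        if not (1 <= bp <= n_bp):
            raise ValidationError(f"base pair {bp} outside 1..{n_bp}")
        r1 = res1[bp - 1]
        r2 = res2[n_bp - bp]
        m = (((s.chain_ids == spec.strand1_chain) & (s.res_ids == r1))
             | ((s.chain_ids == spec.strand2_chain) & (s.res_ids == r2)))
        if heavy_only:
            m &= s.is_heavy
        idx = np.flatnonzero(m)
        if idx.size == 0:
            raise ValidationError(f"base pair {bp}: residues {r1}/{r2} "
                                  "resolve to no atoms")
        return idx

    out: dict[str, DistanceSeries] = {}
    for lo, hi in spec.windows:
        seg1 = np.concatenate([bp_atoms(bp) for bp in range(lo, hi + 1)])
        seg2 = np.concatenate([bp_atoms(n_bp + 1 - bp)
                               for bp in range(lo, hi + 1)])
        w1 = s.masses[seg1] / s.masses[seg1].sum()
        w2 = s.masses[seg2] / s.masses[seg2].sum()
        com1 = np.einsum("fij,i->fj", traj.coords_nm[:, seg1, :], w1)
        com2 = np.einsum("fij,i->fj", traj.coords_nm[:, seg2, :], w2)
        dist = np.linalg.norm(com1 - com2, axis=1)
        label = f"{lo}-{hi}bp"
        out[label] = DistanceSeries(times_ps=traj.times_ps.copy(),
                                    values=dist, label=label)
    return out


def running_average(series: DistanceSeries,
                    window_ps: float = 200.0) -> DistanceSeries:
    """Trailing mean over all frames within the preceding ``window_ps``.

    The output keeps the input time base.  The window must exceed the
    frame spacing; a single-frame series is returned unchanged with a
    warning.
    """
    t = series.times_ps
    v = series.values
    if len(t) < 2:
        warnings.warn("single-frame series: running average is the identity")
        return DistanceSeries(t.copy(), v.copy(), series.label)
    spacing = np.min(np.diff(t))
    if window_ps <= spacing:
        raise ValidationError(
            f"window {window_ps} ps must exceed frame spacing {spacing} ps")
    out = np.empty_like(v, dtype=float)
    lo = 0
    csum = np.concatenate(([0.0], np.cumsum(v)))
    for i, ti in enumerate(t):
        while t[lo] <= ti - window_ps:
            lo += 1
        out[i] = (csum[i + 1] - csum[lo]) / (i + 1 - lo)
    return DistanceSeries(t.copy(), out, series.label)


def contact_probability(traj: Trajectory, residue: tuple[str, int],
                        neighbors: AtomSelection,
                        d_cut_nm: float = CONTACT_DIST_NM) -> pd.DataFrame:
    """Per-neighbor-residue contact probability for one residue.

    For every residue in ``neighbors`` (the reference residue itself is
    excluded), the fraction of frames with at least one heavy-atom pair
    within ``d_cut_nm`` of the reference residue.  Run separately per
    histone copy by passing that copy's chain id.
    """
    s = traj.structure
    chain, resid = residue
    ref = np.flatnonzero((s.chain_ids == chain) & (s.res_ids == resid)
                         & s.is_heavy)
    if ref.size == 0:
        raise ValidationError(f"residue {chain}/{resid} not found (heavy)")
    nb_idx = neighbors.indices(s)
    nb_idx = nb_idx[s.is_heavy[nb_idx]]
    nb_idx = nb_idx[~((s.chain_ids[nb_idx] == chain)
                      & (s.res_ids[nb_idx] == resid))]
    rows = []
    keys = sorted({(str(s.chain_ids[i]), int(s.res_ids[i])) for i in nb_idx})
    for ch, ri in keys:
        grp = nb_idx[(s.chain_ids[nb_idx] == ch) & (s.res_ids[nb_idx] == ri)]
        hits = 0
        for fi in range(traj.n_frames):
            xyz = traj.coords_nm[fi]
            d = _pair_dists(xyz[ref], xyz[grp], traj.box_nm)
            if np.any(d < d_cut_nm):
                hits += 1
        rows.append({"chain": ch, "resid": ri,
                     "probability": hits / traj.n_frames})
    return pd.DataFrame(rows)
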