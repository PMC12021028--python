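"""Structural-repeat analysis of long chain models.

A mucin-like chain built from tandem copies of one fold is segmented by
superposition: a seed domain is slid along the chain, windows that superpose
onto it within an RMSD cutoff mark repeat instances, and boundaries are
refined from the per-column deviation profile.  The segments then feed an
all-vs-all RMSD matrix, a structure-guided multiple sequence alignment,
conserved-column detection (the conserved cysteine pair), disulfide
detection from Sγ distances, and sequence-identity statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FitError, ParameterError, ValidationError
from .structure import StructureModel

__all__ = [
    "SuperpositionResult",
    "kabsch_superpose",
    "DomainSegment",
    "segment_repeats",
    "RmsdMatrix",
    "pairwise_rmsd_matrix",
    "StructureMSA",
    "structure_guided_msa",
    "find_conserved_columns",
    "DisulfideBond",
    "detect_disulfides",
    "global_identity",
    "repeat_stats",
]

GAP = "-"


# ---------------------------------------------------------------------------
# rigid superposition


@dataclass
class SuperpositionResult:
    """Optimal least-squares rigid superposition of paired point sets.

    ``rotation`` (3x3, det = +1) and ``translation`` map set B onto set A:
    ``B @ rotation.T + translation ≈ A``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    correspondence: list[tuple[int, int]]


def kabsch_superpose(coords_a, coords_b, correspondence=None) -> SuperpositionResult:
    """Kabsch superposition of B onto A (equal-length paired points).

    Uses the SVD of the cross-covariance with a determinant sign correction,
    so the returned rotation is always proper (no reflection), even for
    mirror-image inputs.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise FitError(f"point sets must both be (n, 3); got {A.shape} and {B.shape}")
    n = len(A)
    if n < 3:
        raise FitError("need at least 3 point pairs")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    sv_a = np.linalg.svd(A0, compute_uv=False)
    if sv_a[1] < 1e-9 * max(sv_a[0], 1.0):
        raise FitError("degenerate geometry: points are (nearly) collinear")
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    diff = (B @ R.T + t) - A
    rmsd = float(np.sqrt((diff**2).sum() / n))
    if correspondence is None:
        correspondence = [(i, i) for i in range(n)]
    return SuperpositionResult(R, t, rmsd, list(correspondence))


def _window_rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """RMSD of the optimal superposition, degenerate windows -> inf."""
    try:
        return kabsch_superpose(A, B).rmsd
    except FitError:
        return float("inf")


def _trimmed_superpose(A: np.ndarray, B: np.ndarray, n_iter: int = 3):
    """Superpose B onto A, iteratively down-weighting outlier pairs.

    Returns ``(result, inlier_mask)`` where the result is fitted on the
    inliers only (residues whose deviation stays below twice the median).
    """
    mask = np.ones(len(A), dtype=bool)
    res = kabsch_superpose(A, B)
    for _ in range(n_iter):
        dev = np.linalg.norm((B @ res.rotation.T + res.translation) - A, axis=1)
        med = np.median(dev[mask])
        new_mask = dev <= max(2.0 * med, 1.0)
        if new_mask.sum() < 3 or np.array_equal(new_mask, mask):
            break
        mask = new_mask
        res = kabsch_superpose(A[mask], B[mask])
    dev = np.linalg.norm((B @ res.rotation.T + res.translation) - A, axis=1)
    rmsd_in = float(np.sqrt((dev[mask] ** 2).mean()))
    out = SuperpositionResult(res.rotation, res.translation, rmsd_in,
                              [(i, i) for i in np.flatnonzero(mask)])
    return out, mask


# ---------------------------------------------------------------------------
# repeat segmentation


@dataclass(frozen=True)
class DomainSegment:
    """1-based inclusive residue range of one repeat in a chain."""

    start: int
    end: int
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"segment start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def slice(self) -> slice:
        return slice(self.start - 1, self.end)


def _pick_seed(ca: np.ndarray, window: int, cutoff: float, stride: int) -> int:
    """Best seed start (0-based): the window whose copies are most frequent."""
    L = len(ca)
    starts = list(range(0, L - window + 1, stride))
    best_start, best_score = 0, (-1, np.inf)
    for s in starts:
        seed = ca[s : s + window]
        hits, total = 0, 0.0
        for s2 in starts:
            if abs(s2 - s) < window // 2:
                continue
            r = _window_rmsd(seed, ca[s2 : s2 + window])
            if r <= cutoff:
                hits += 1
                total += r
        score = (-hits, total)
        if score < best_score:
            best_score, best_start = score, s
    return best_start


def segment_repeats(
    model: StructureModel,
    seed_hint: DomainSegment | None = None,
    min_len: int = 80,
    max_len: int = 140,
    rmsd_cutoff: float = 3.5,
    min_coverage: float = 0.7,
) -> list[DomainSegment]:
    """Find the maximal ordered set of non-overlapping structural repeats.

    A seed window (user hint, else the self-similarity-optimal window of
    length ``(min_len + max_len) // 2``) is slid along the chain; window
    starts whose trimmed superposition onto the seed keeps >= ``min_coverage``
    of residues below the RMSD cutoff are candidate repeats.  Non-overlapping
    local minima of the RMSD profile are selected greedily in ascending RMSD,
    and boundaries are refined by trimming window columns whose cross-repeat
    deviation exceeds the consensus (linker contamination).
    Returns an empty list (with no exception) when no repeating seed exists.
    """
    ca = model.ca
    L = len(ca)
    if L < min_len:
        return []
    window = (min_len + max_len) // 2
    if seed_hint is not None:
        window = min(len(seed_hint), L)
        seed_start = seed_hint.start - 1
    else:
        window = min(window, L)
        seed_start = _pick_seed(ca, window, rmsd_cutoff, stride=max(window // 8, 1))
    seed = ca[seed_start : seed_start + window]

    # pass 1: detect repeat instances of the nominal window
    chosen = _profile_minima(ca, seed, rmsd_cutoff, min_coverage)
    if not chosen:
        return []

    # trim window columns that do not repeat (linker contamination), giving
    # the conserved core of the repeat unit
    lead_trim, tail_trim = _column_trim(ca, seed, chosen, window)
    core = seed[lead_trim : window - tail_trim]
    if len(core) < max(3, int(min_len * 0.5)):
        core = seed
        lead_trim = tail_trim = 0

    # pass 2: re-scan with the core seed (it fits repeats that a too-long
    # nominal window would overrun, e.g. the last repeat of the chain)
    if len(core) < window:
        chosen = _profile_minima(ca, core, rmsd_cutoff, min_coverage)
        if not chosen:
            return []
    else:
        chosen = [s + lead_trim for s in chosen]

    w = len(core)
    segments = []
    prev_end = 0
    for s in sorted(chosen):
        start, end = s + 1, s + w  # to 1-based inclusive
        if start <= prev_end:  # enforce non-overlap after refinement
            start = prev_end + 1
        if end - start + 1 >= 3:
            segments.append(DomainSegment(start, end, model.chain_id))
            prev_end = end
    return segments


def _profile_minima(ca, seed, rmsd_cutoff, min_coverage, overlap_tol: float = 0.12):
    """Starts of non-overlapping windows that superpose onto the seed.

    The trimmed-superposition RMSD profile is scanned over every start;
    qualifying starts are selected greedily in ascending RMSD, each
    suppressing later starts closer than ``(1 - overlap_tol) * window``
    (a small tolerated overlap absorbs seed windows slightly longer than
    the true repeat period; overlaps are clipped after refinement).
    """
    L = len(ca)
    window = len(seed)
    n_starts = L - window + 1
    if n_starts < 1:
        return []
    profile = np.full(n_starts, np.inf)
    for s in range(n_starts):
        try:
            res, mask = _trimmed_superpose(seed, ca[s : s + window])
        except FitError:
            continue
        if mask.mean() >= min_coverage and res.rmsd <= rmsd_cutoff:
            profile[s] = res.rmsd
    min_gap = int(np.ceil((1.0 - overlap_tol) * window))
    order = np.argsort(profile, kind="stable")
    chosen: list[int] = []
    for s in order:
        if not np.isfinite(profile[s]):
            break
        if all(abs(s - c) >= min_gap for c in chosen):
            chosen.append(int(s))
    return sorted(chosen)


def _column_trim(ca, seed, starts, window, factor: float = 3.0):
    """How many leading/trailing window columns are linker contamination.

    Columns whose mean superposed deviation across repeats exceeds
    ``factor`` x the core median are trimmed from both ends.
    """
    if len(starts) < 2:
        return 0, 0
    devs = []
    for s in starts:
        win = ca[s : s + window]
        try:
            res, _ = _trimmed_superpose(seed, win)
        except FitError:
            continue
        devs.append(np.linalg.norm((win @ res.rotation.T + res.translation) - seed, axis=1))
    if not devs:
        return 0, 0
    col = np.mean(devs, axis=0)
    core = np.median(col)
    bad = col > max(factor * core, 1.5)
    lead = 0
    while lead < window // 4 and bad[lead]:
        lead += 1
    tail = 0
    while tail < window // 4 and bad[window - 1 - tail]:
        tail += 1
    return lead, tail


# ---------------------------------------------------------------------------
# pairwise RMSD matrix and structure-guided MSA


@dataclass
class RmsdMatrix:
    """Symmetric k x k Cα RMSD matrix over repeat segments (Å)."""

    values: np.ndarray
    segments: list[DomainSegment]

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("RMSD matrix must be square")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValidationError("RMSD matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValidationError("RMSD matrix diagonal must be zero")

    def to_frame(self):
        import pandas as pd

        labels = [f"{s.start}-{s.end}" for s in self.segments]
        return pd.DataFrame(self.values, index=labels, columns=labels)


@dataclass
class StructureMSA:
    """Structure-guided alignment: one row per segment, columns = reference
    residues (1-based on the reference segment)."""

    rows: list[str]
    segments: list[DomainSegment]
    reference_index: int

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValidationError("all MSA rows must have the same length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, index: int) -> str:
        """Column by 1-based index."""
        return "".join(row[index - 1] for row in self.rows)

    def column_frequencies(self, index: int) -> dict[str, float]:
        """Non-gap residue frequencies in a 1-based column (sum to 1)."""
        col = [c for c in self.column(index) if c != GAP]
        if not col:
            return {}
        return {aa: col.count(aa) / len(col) for aa in sorted(set(col))}


def _align_segment_pair(ca_ref, ca_seg, max_dist: float = 5.0):
    """Nearest-Cα correspondence (< max_dist Å) after iterative superposition.

    Returns a dict: segment residue offset -> reference residue offset.
    """
    n = min(len(ca_ref), len(ca_seg))
    # bootstrap with the sequential correspondence, then re-pair by distance
    res, _ = _trimmed_superpose(ca_ref[:n], ca_seg[:n])
    moved = ca_seg @ res.rotation.T + res.translation
    for _ in range(2):
        d = np.linalg.norm(moved[:, None, :] - ca_ref[None, :, :], axis=2)
        pairs = []
        for i in range(len(ca_seg)):
            j = int(np.argmin(d[i]))
            if d[i, j] < max_dist:
                pairs.append((i, j, d[i, j]))
        if len(pairs) < 3:
            return {}
        idx_s = np.array([p[0] for p in pairs])
        idx_r = np.array([p[1] for p in pairs])
        fit = kabsch_superpose(ca_ref[idx_r], ca_seg[idx_s])
        moved = ca_seg @ fit.rotation.T + fit.translation
    # final pairing, unique per reference column, closest-distance first
    d = np.linalg.norm(moved[:, None, :] - ca_ref[None, :, :], axis=2)
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    mapping: dict[int, int] = {}
    used_ref: set[int] = set()
    for i, j in order:
        if d[i, j] >= max_dist:
            break
        if i in mapping or j in used_ref:
            continue
        mapping[int(i)] = int(j)
        used_ref.add(int(j))
    return mapping


def structure_guided_msa(
    model: StructureModel,
    segments: list[DomainSegment],
    reference_index: int = 0,
) -> StructureMSA:
    """Align repeat sequences by superposing each segment onto a reference.

    Each segment's residues are assigned to reference columns by nearest-Cα
    pairing (< 5 Å) after rigid superposition; reference residues with no
    partner show a gap in that row.  Segments that fail to superpose give an
    all-gap row.
    """
    if not segments:
        raise ParameterError("need at least one segment")
    if not (0 <= reference_index < len(segments)):
        raise ParameterError("reference index out of range")
    ref = segments[reference_index]
    ca_ref = model.ca[ref.slice()]
    seq = model.sequence
    m = len(ref)
    rows = []
    for k, seg in enumerate(segments):
        if k == reference_index:
            rows.append(seq[ref.slice()])
            continue
        ca_seg = model.ca[seg.slice()]
        mapping = _align_segment_pair(ca_ref, ca_seg)
        row = [GAP] * m
        seg_seq = seq[seg.slice()]
        for i, j in mapping.items():
            row[j] = seg_seq[i]
        rows.append("".join(row))
    return StructureMSA(rows, list(segments), reference_index)


def pairwise_rmsd_matrix(model: StructureModel, segments: list[DomainSegment]) -> RmsdMatrix:
    """All-vs-all Cα RMSD of repeat segments on the MSA correspondence.

    For each pair, residues aligned to the same reference column in the
    structure-guided MSA are superposed by Kabsch; pairs with fewer than 3
    shared columns are flagged missing (NaN).
    """
    if len(segments) < 2:
        raise ParameterError("need at least 2 segments")
    msa = structure_guided_msa(model, segments, 0)
    # per-segment: reference column -> residue offset
    maps = []
    ref = segments[0]
    for k, seg in enumerate(segments):
        if k == 0:
            maps.append({j: j for j in range(len(ref))})
        else:
            ca_seg = model.ca[seg.slice()]
            maps.append({j: i for i, j in _align_segment_pair(model.ca[ref.slice()], ca_seg).items()})
    k = len(segments)
    out = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            shared = sorted(set(maps[a]) & set(maps[b]))
            if len(shared) < 3:
                out[a, b] = out[b, a] = np.nan
                continue
            A = model.ca[segments[a].slice()][[maps[a][c] for c in shared]]
            B = model.ca[segments[b].slice()][[maps[b][c] for c in shared]]
            r = _window_rmsd(A, B)
            out[a, b] = out[b, a] = r
    return RmsdMatrix(out, list(segments))


def find_conserved_columns(msa: StructureMSA, residue: str, min_frequency: float) -> list[int]:
    """1-based MSA columns where ``residue`` occurs and its non-gap frequency
    is >= ``min_frequency``."""
    if not (0 < min_frequency <= 1) and min_frequency != 0:
        raise ParameterError("min_frequency must be in [0, 1]")
    residue = residue.upper()
    out = []
    for c in range(1, msa.n_columns + 1):
        freqs = msa.column_frequencies(c)
        if freqs.get(residue, 0.0) > 0 and freqs.get(residue, 0.0) >= min_frequency:
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# disulfides


@dataclass(frozen=True)
class DisulfideBond:
    """Cys–Cys bond: 1-based residue indices and Sγ–Sγ distance (Å)."""

    residue_a: int
    residue_b: int
    distance: float


def detect_disulfides(model: StructureModel, cutoff: float = 2.5) -> list[DisulfideBond]:
    """Greedy closest-pair disulfide assignment from Sγ–Sγ distances.

    All Cys pairs within ``cutoff`` Å are sorted by distance; each cysteine
    joins at most one bond.
    """
    cys = [
        i + 1
        for i, name in enumerate(model.resnames)
        if name.upper() == "CYS" and model.sg_of(i + 1) is not None
    ]
    pairs = []
    for ai in range(len(cys)):
        for bi in range(ai + 1, len(cys)):
            a, b = cys[ai], cys[bi]
            d = float(np.linalg.norm(model.sg_of(a) - model.sg_of(b)))
            if d <= cutoff:
                pairs.append((d, a, b))
    pairs.sort()
    used: set[int] = set()
    bonds = []
    for d, a, b in pairs:
        if a in used or b in used:
            continue
        used.update((a, b))
        bonds.append(DisulfideBond(a, b, d))
    return bonds


# ---------------------------------------------------------------------------
# sequence identity


_VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


def global_identity(
    seq_a: str,
    seq_b: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Percent identity from a global Needleman–Wunsch alignment (BLOSUM62).

    Identity = identical columns / alignment length x 100, gaps counted in
    the denominator.  Gap penalties are positive magnitudes.
    """
    for name, s in (("first", seq_a), ("second", seq_b)):
        if not s:
            raise ParameterError(f"{name} sequence is empty")
        bad = sorted(set(s.upper()) - _VALID_AA)
        if bad:
            raise ParameterError(
                f"{name} sequence has non-amino-acid symbol(s): {', '.join(bad)}"
            )
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    a, b = str(aln[0]), str(aln[1])
    same = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return 100.0 * same / len(a)


def msa_pairwise_identity(row_a: str, row_b: str) -> float:
    """Percent identity between two MSA rows over all columns (gaps count in
    the denominator; two gaps never match)."""
    same = sum(1 for x, y in zip(row_a, row_b) if x == y and x != GAP)
    return 100.0 * same / len(row_a)


def repeat_stats(segments: list[DomainSegment], msa: StructureMSA | None = None) -> dict:
    """Count, length mean ± SD, and mean pairwise identity of a repeat set."""
    if not segments:
        raise ParameterError("need at least one segment")
    lengths = np.array([len(s) for s in segments], dtype=float)
    out = {
        "count": len(segments),
        "length_mean": float(lengths.mean()),
        "length_sd": float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0,
        "identity_convention": "identical columns / alignment length (gaps in denominator)",
    }
    if msa is not None and len(msa.rows) >= 2:
        vals = [
            msa_pairwise_identity(msa.rows[i], msa.rows[j])
            for i in range(len(msa.rows))
            for j in range(i + 1, len(msa.rows))
        ]
        out["mean_pairwise_identity"] = float(np.mean(vals))
    return out
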