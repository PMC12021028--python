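"""Synthetic chains of near-identical structural repeats.

Emulates a mucin-like protein built from ~100-residue Ig-like domains that
share the same fold but little sequence: k noisy rigid copies of one template
domain, each randomly re-oriented and connected by short extended linkers,
with sequences mutated to a requested mean pairwise identity except at
planted invariant positions (a conserved cysteine pair by default, whose Sγ
atoms form one intra-domain disulfide per repeat).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..errors import ParameterError, ValidationError
from ..structure import StructureModel, one_to_three

__all__ = ["RepeatChainSpec", "default_domain_template", "simulate_repeat_chain"]

# 19 standard amino acids excluding Cys; Cys is reserved for planted
# invariant positions so no other column can become all-Cys by chance.
_ALPHABET = "ADEFGHIKLMNPQRSTVWY"

_CA_SPACING = 3.8  # Å, consecutive Cα distance


def default_domain_template(n_residues: int = 100, radius: float = 13.0) -> np.ndarray:
    """Deterministic compact 'globular' Cα fold: a spherical spiral.

    Consecutive Cα points are ~3.8 Å apart on a sphere of the given radius,
    winding pole to pole.  Not a real protein fold, but compact, chiral and
    asymmetric — enough for superposition-based repeat detection to have the
    same signal structure as a real Ig-like domain.
    """
    # choose the number of turns so that total arc length fits n points
    arc_needed = (n_residues - 1) * _CA_SPACING
    # spherical spiral arc length ~ integral of sqrt((r θ')² sin².. ); solve
    # numerically by scaling the turn count
    turns = arc_needed / (2 * math.pi * radius) * 1.35
    t = np.linspace(0.0, 1.0, 20000)
    theta = t * math.pi
    phi = 2 * math.pi * turns * t
    pts = radius * np.stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)],
        axis=1,
    )
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    # re-sample at equal arc length, then rescale so spacing is ~3.8 Å
    targets = np.linspace(0.0, arc[-1], n_residues)
    out = np.empty((n_residues, 3))
    for k in range(3):
        out[:, k] = np.interp(targets, arc, pts[:, k])
    # fixed aperiodic radial modulation: a bare spiral is translationally
    # self-similar (like a helix), which would make shift-by-one residue
    # registrations superpose almost as well as the true one; real globular
    # folds are not shift-symmetric, so break the symmetry deterministically
    bumps = np.random.default_rng(1234).uniform(-2.0, 2.0, size=n_residues)
    radial = out / np.maximum(np.linalg.norm(out, axis=1, keepdims=True), 1e-9)
    out = out + radial * bumps[:, None]
    mean_spacing = np.linalg.norm(np.diff(out, axis=0), axis=1).mean()
    out *= _CA_SPACING / mean_spacing
    return out - out.mean(axis=0)


@dataclass
class RepeatChainSpec:
    """Conditions for one synthetic repeat chain.

    ``pairwise_identity`` is the target *mean pairwise* percent identity
    between repeat sequences — the quantity reported for real repeat
    families — realized internally by mutating each repeat away from a
    common template sequence at a solved-for rate.  ``invariant_positions``
    (1-based template positions) are planted as cysteines in every repeat.
    """

    n_template_residues: int = 100
    k: int = 5
    linker_length: int = 8
    pairwise_identity: float = 22.0
    invariant_positions: tuple[int, ...] = (60, 91)
    coord_noise: float = 0.3  # Å, isotropic Gaussian on each Cα
    seed: int = 0
    template_ca: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if not (0.0 <= self.pairwise_identity <= 100.0):
            raise ValidationError("pairwise identity must be in [0, 100]")
        if self.template_ca is None:
            self.template_ca = default_domain_template(self.n_template_residues)
        else:
            self.template_ca = np.asarray(self.template_ca, dtype=float)
            self.n_template_residues = len(self.template_ca)
        if self.n_template_residues < 20:
            raise ValidationError("template must have >= 20 residues")
        for p in self.invariant_positions:
            if not (1 <= p <= self.n_template_residues):
                raise ValidationError(f"invariant position {p} outside template")


def _keep_fraction(spec: RepeatChainSpec) -> float:
    """Solve for the per-repeat fraction of non-invariant template positions
    kept, so that the expected mean pairwise identity matches the target.

    Two repeats match at a non-invariant position if both kept it (p²) or
    both mutated it to the same of the 18 non-template letters ((1-p)²/18).
    """
    n = spec.n_template_residues
    c = len(spec.invariant_positions)
    y = (spec.pairwise_identity / 100.0 * n - c) / (n - c)
    if y > 1.0:
        y = 1.0
    disc = 1.0 - 19.0 * (1.0 - 18.0 * y)
    if y < 0 or disc < 0:
        raise ParameterError(
            f"pairwise identity {spec.pairwise_identity}% is incompatible with "
            f"{c} planted invariant position(s) (minimum achievable ≈ "
            f"{100 * (c + (n - c) / 19.0) / n:.1f}%)"
        )
    p = (1.0 + math.sqrt(disc)) / 19.0
    return min(p, 1.0)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def _mutate_sequence(template_seq: list[str], keep: np.ndarray, rng) -> list[str]:
    seq = list(template_seq)
    for i in np.flatnonzero(~keep):
        choices = [a for a in _ALPHABET if a != seq[i]]
        seq[i] = choices[rng.integers(len(choices))]
    return seq


def simulate_repeat_chain(spec: RepeatChainSpec):
    """Generate a repeat chain with known boundaries and sequences.

    Returns ``(StructureModel, boundaries, records)`` where ``boundaries`` is
    a list of 1-based inclusive ``(start, end)`` residue ranges of the k
    repeats in the concatenated chain, and ``records`` are ``(name, seq)``
    FASTA-ready tuples (full chain first, then one per repeat).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_template_residues
    template = spec.template_ca - spec.template_ca.mean(axis=0)
    p_keep = _keep_fraction(spec)
    inv_idx = np.array([p - 1 for p in spec.invariant_positions], dtype=int)

    # template sequence: Cys only at invariant positions
    template_seq = [_ALPHABET[i] for i in rng.integers(len(_ALPHABET), size=n)]
    for i in inv_idx:
        template_seq[i] = "C"

    extent = float(np.ptp(template, axis=0).max())
    gap = max(spec.linker_length + 1, 2) * 3.2  # span bridged by the linker

    coords: list[np.ndarray] = []
    names: list[str] = []
    sg: list[np.ndarray] = []
    boundaries: list[tuple[int, int]] = []
    records: list[tuple[str, str]] = []
    repeat_seqs: list[str] = []

    anchor = np.zeros(3)  # where the next domain's first Cα goes
    for rep in range(spec.k):
        R = _random_rotation(rng)
        dom = template @ R.T
        dom = dom + rng.normal(0.0, spec.coord_noise, size=dom.shape)
        dom = dom - dom[0] + anchor
        # sequence: keep an exact count of non-invariant positions (lower
        # variance of the realized pairwise identity than Bernoulli keeps)
        non_inv = np.setdiff1d(np.arange(n), inv_idx)
        m_keep = int(round(p_keep * len(non_inv)))
        keep = np.zeros(n, dtype=bool)
        keep[rng.permutation(non_inv)[:m_keep]] = True
        keep[inv_idx] = True
        seq = _mutate_sequence(template_seq, keep, rng)
        repeat_seqs.append("".join(seq))

        start = len(coords) + 1
        coords.extend(dom)
        names.extend(one_to_three(a) for a in seq)
        # Sγ: invariant pair forms one intra-domain disulfide (2.05 Å)
        sg_block = np.full((n, 3), np.nan)
        if len(inv_idx) >= 2:
            a, b = inv_idx[0], inv_idx[1]
            mid = (dom[a] + dom[b]) / 2.0
            axis = dom[b] - dom[a]
            axis = axis / max(np.linalg.norm(axis), 1e-9)
            sg_block[a] = mid - axis * 1.025
            sg_block[b] = mid + axis * 1.025
        elif len(inv_idx) == 1:
            sg_block[inv_idx[0]] = dom[inv_idx[0]] + np.array([1.8, 0, 0])
        sg.extend(sg_block)
        boundaries.append((start, start + n - 1))

        if rep < spec.k - 1:
            # extended linker: straight walk from the domain's last Cα to the
            # next domain's first Cα, with small jitter
            direction = np.array([1.0, 0.35 * np.sin(rep + 1.0), 0.25 * np.cos(2.0 * rep)])
            direction /= np.linalg.norm(direction)
            lstart = dom[-1]
            for j in range(1, spec.linker_length + 1):
                pt = lstart + direction * (j * gap / (spec.linker_length + 1))
                pt = pt + rng.normal(0.0, spec.coord_noise, size=3)
                coords.append(pt)
                names.append(one_to_three("G" if j % 2 else "S"))
                sg.append(np.full(3, np.nan))
            anchor = lstart + direction * gap

    model = StructureModel(
        chain_id="A",
        resnames=names,
        ca=np.array(coords),
        sg=np.array(sg),
    )
    full_seq = model.sequence
    records.append(("chain_full", full_seq))
    for i, s in enumerate(repeat_seqs, start=1):
        records.append((f"repeat_{i:02d}", s))
    return model, boundaries, records
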