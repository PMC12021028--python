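"""Kabsch superposition, repeat segmentation, RMSD matrices, structure-guided
alignment, conserved columns, disulfides and sequence identity."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ciliacoat.errors import FitError, ParameterError
from ciliacoat.repeats import (
    DomainSegment,
    detect_disulfides,
    find_conserved_columns,
    global_identity,
    kabsch_superpose,
    msa_pairwise_identity,
    pairwise_rmsd_matrix,
    repeat_stats,
    segment_repeats,
    structure_guided_msa,
)
from ciliacoat.structure import StructureModel
from ciliacoat.synthetic import RepeatChainSpec, simulate_repeat_chain


def _cloud(rng, n=20):
    return rng.normal(0, 5, (n, 3))


class TestKabsch:
    def test_identical_sets_give_zero_rmsd_identity_rotation(self, rng):
        A = _cloud(rng)
        res = kabsch_superpose(A, A)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-12)

    def test_rotation_and_translation_recovered_exactly(self, rng):
        A = _cloud(rng)
        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        B = (A - A.mean(0)) @ R + A.mean(0) + np.array([5.0, -3.0, 2.0])
        res = kabsch_superpose(A, B)
        assert res.rmsd < 1e-9
        # B = A0 @ R + shift  =>  the recovered rotation equals R
        np.testing.assert_allclose(res.rotation, R, atol=1e-9)

    def test_mirror_input_still_returns_proper_rotation(self, rng):
        A = _cloud(rng)
        B = A * np.array([1.0, 1.0, -1.0])
        res = kabsch_superpose(A, B)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
        assert res.rmsd > 0

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(FitError):
            kabsch_superpose(_cloud(rng, 10), _cloud(rng, 12))

    def test_collinear_points_rejected(self):
        line = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        with pytest.raises(FitError, match="collinear"):
            kabsch_superpose(line, line + 1.0)

    def test_optimality_against_random_rigid_probes(self, rng):
        """Kabsch RMSD is never beaten by random rigid transforms."""
        A = _cloud(rng, 30)
        B = _cloud(rng, 30)
        best = kabsch_superpose(A, B).rmsd
        for _ in range(200):
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.normal(0, 3, 3)
            rmsd = np.sqrt((((B @ R.T + t) - A) ** 2).sum() / len(A))
            assert rmsd >= best - 1e-9

    def test_agrees_with_scipy_align_vectors(self, rng):
        A = _cloud(rng, 25)
        B = _cloud(rng, 25)
        res = kabsch_superpose(A, B)
        rot, rssd = Rotation.align_vectors(A - A.mean(0), B - B.mean(0))
        assert res.rmsd == pytest.approx(rssd / np.sqrt(len(A)), rel=1e-9)
        np.testing.assert_allclose(res.rotation, rot.as_matrix(), atol=1e-8)


class TestSegmentation:
    def test_recovers_boundaries_on_noisy_chain(self, repeat_chain_k5):
        _, model, bounds, _ = repeat_chain_k5
        segs = segment_repeats(model)
        assert len(segs) == len(bounds)
        for seg, (s, e) in zip(segs, bounds):
            assert abs(seg.start - s) <= 5
            assert abs(seg.end - e) <= 5

    def test_short_chain_yields_empty(self):
        model, _, _ = simulate_repeat_chain(RepeatChainSpec(k=1, seed=0))
        short = StructureModel("A", model.resnames[:50], model.ca[:50])
        assert segment_repeats(short, min_len=80) == []

    def test_idempotent_with_seed_hint(self, repeat_chain_k5):
        """Re-running with the first found segment as hint reproduces the
        same boundaries."""
        _, model, _, _ = repeat_chain_k5
        first = segment_repeats(model)
        second = segment_repeats(model, seed_hint=first[0])
        assert [(s.start, s.end) for s in second] == [
            (s.start, s.end) for s in first
        ]

    def test_boundary_accuracy_degrades_monotonically_with_noise(self):
        """Repeat count recovered never increases and boundary error never
        decreases as coordinate noise grows."""
        errs, counts = [], []
        for noise in (0.1, 1.0, 3.0):
            model, bounds, _ = simulate_repeat_chain(
                RepeatChainSpec(k=5, coord_noise=noise, seed=77)
            )
            segs = segment_repeats(model)
            counts.append(len(segs))
            if len(segs) == len(bounds):
                errs.append(
                    max(
                        max(abs(s.start - b[0]), abs(s.end - b[1]))
                        for s, b in zip(segs, bounds)
                    )
                )
            else:
                errs.append(np.inf)
        assert counts[0] >= counts[-1]
        assert errs[0] <= errs[-1] + 1  # allow one-residue jitter


class TestRmsdMatrix:
    def test_identical_copies_give_zero_offdiagonal(self):
        model, bounds, _ = simulate_repeat_chain(
            RepeatChainSpec(k=4, coord_noise=0.0, seed=3)
        )
        segs = [DomainSegment(a, b) for a, b in bounds]
        rm = pairwise_rmsd_matrix(model, segs)
        off = rm.values[np.triu_indices(4, 1)]
        np.testing.assert_allclose(off, 0.0, atol=1e-9)

    def test_symmetry_and_zero_diagonal(self, repeat_chain_k5):
        _, model, bounds, _ = repeat_chain_k5
        rm = pairwise_rmsd_matrix(model, [DomainSegment(a, b) for a, b in bounds])
        np.testing.assert_array_equal(rm.values, rm.values.T)
        np.testing.assert_allclose(np.diag(rm.values), 0.0)

    def test_noise_implied_rmsd_level(self):
        """With 0.5 Å coordinate noise the mean pairwise RMSD matches a
        Monte-Carlo oracle of noisy template pairs."""
        noise = 0.5
        model, bounds, _ = simulate_repeat_chain(
            RepeatChainSpec(k=5, coord_noise=noise, seed=21)
        )
        rm = pairwise_rmsd_matrix(model, [DomainSegment(a, b) for a, b in bounds])
        got = float(np.nanmean(rm.values[np.triu_indices(5, 1)]))
        # oracle: superpose pairs of independently noisy template copies
        rng = np.random.default_rng(0)
        template = RepeatChainSpec(k=2, seed=0).template_ca
        sims = []
        for _ in range(40):
            a = template + rng.normal(0, noise, template.shape)
            b = template + rng.normal(0, noise, template.shape)
            sims.append(kabsch_superpose(a, b).rmsd)
        oracle = float(np.mean(sims))
        assert got == pytest.approx(oracle, abs=0.3)


class TestStructureMSA:
    def test_identical_domains_align_gap_free(self):
        model, bounds, _ = simulate_repeat_chain(
            RepeatChainSpec(k=4, coord_noise=0.0, seed=5)
        )
        msa = structure_guided_msa(model, [DomainSegment(a, b) for a, b in bounds])
        assert len(msa.rows) == 4
        assert all("-" not in row for row in msa.rows)

    def test_planted_cys_columns_fully_conserved(self, repeat_chain_k5):
        _, model, bounds, _ = repeat_chain_k5
        msa = structure_guided_msa(model, [DomainSegment(a, b) for a, b in bounds])
        assert find_conserved_columns(msa, "C", 1.0) == [60, 91]

    def test_row_count_equals_segment_count(self, repeat_chain_k5):
        _, model, bounds, _ = repeat_chain_k5
        segs = [DomainSegment(a, b) for a, b in bounds]
        assert len(structure_guided_msa(model, segs).rows) == len(segs)

    def test_column_frequencies_sum_to_one(self, repeat_chain_k5):
        _, model, bounds, _ = repeat_chain_k5
        msa = structure_guided_msa(model, [DomainSegment(a, b) for a, b in bounds])
        for c in (1, 30, 60, 91, msa.n_columns):
            freqs = msa.column_frequencies(c)
            if freqs:
                assert sum(freqs.values()) == pytest.approx(1.0)


class TestConservedColumns:
    def _msa(self, rows):
        from ciliacoat.repeats import StructureMSA

        segs = [DomainSegment(1, len(rows[0]))] * len(rows)
        return StructureMSA(rows, segs, 0)

    def test_full_conservation_exact_columns(self):
        msa = self._msa(["ACDA", "ACEA", "GCDA"])
        assert find_conserved_columns(msa, "C", 1.0) == [2]
        assert find_conserved_columns(msa, "A", 1.0) == [4]

    def test_empty_alignment(self):
        from ciliacoat.repeats import StructureMSA

        msa = StructureMSA([], [], 0)
        assert find_conserved_columns(msa, "C", 1.0) == []

    def test_zero_frequency_lists_columns_with_any_occurrence(self):
        msa = self._msa(["AC-A", "GAEA"])
        assert find_conserved_columns(msa, "C", 0.0) == [2]
        assert find_conserved_columns(msa, "E", 0.0) == [3]


class TestDisulfides:
    def _model(self, sg_pairs):
        n = 2 * len(sg_pairs)
        names = ["CYS"] * n
        ca = np.arange(n * 3, dtype=float).reshape(n, 3)
        sg = np.zeros((n, 3))
        for i, (a, b) in enumerate(sg_pairs):
            sg[2 * i] = a
            sg[2 * i + 1] = b
        return StructureModel("A", names, ca, sg)

    def test_bonded_pair_detected(self):
        m = self._model([(np.zeros(3), np.array([2.05, 0, 0]))])
        bonds = detect_disulfides(m, cutoff=2.5)
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.05)

    def test_pair_beyond_cutoff_ignored(self):
        m = self._model([(np.zeros(3), np.array([3.5, 0, 0]))])
        assert detect_disulfides(m, cutoff=2.5) == []

    def test_matches_exhaustive_greedy_oracle(self, rng):
        """Random Sγ clouds: greedy closest-pair matches a brute-force oracle
        applying the same rule."""
        for _ in range(10):
            n = 8
            sg = rng.uniform(0, 6, (n, 3))
            m = StructureModel("A", ["CYS"] * n, np.arange(n * 3.0).reshape(n, 3), sg)
            got = {(b.residue_a, b.residue_b) for b in detect_disulfides(m, 3.0)}
            pairs = sorted(
                (np.linalg.norm(sg[i] - sg[j]), i + 1, j + 1)
                for i in range(n)
                for j in range(i + 1, n)
                if np.linalg.norm(sg[i] - sg[j]) <= 3.0
            )
            used, want = set(), set()
            for d, a, b in pairs:
                if a in used or b in used:
                    continue
                used.update((a, b))
                want.add((a, b))
            assert got == want

    def test_chain_disulfide_count(self, repeat_chain_k5):
        _, model, bounds, _ = repeat_chain_k5
        assert len(detect_disulfides(model)) == len(bounds)


def _enumerate_alignments(a, b, matrix, gap_open, gap_extend):
    """All global alignments of tiny sequences with affine gaps, by recursion;
    returns (best score, set of identities among optimal alignments)."""
    best = {"score": -np.inf, "idents": set()}

    def rec(i, j, score, cols, same, prev_gap):
        if i == len(a) and j == len(b):
            total = len(cols)
            if score > best["score"] + 1e-9:
                best["score"] = score
                best["idents"] = {100.0 * same / total}
            elif abs(score - best["score"]) <= 1e-9:
                best["idents"].add(100.0 * same / total)
            return
        if i < len(a) and j < len(b):
            s = matrix[a[i]][b[j]]
            rec(i + 1, j + 1, score + s, cols + [1], same + (a[i] == b[j]), None)
        if i < len(a):
            pen = gap_extend if prev_gap == "a" else gap_open
            rec(i + 1, j, score - pen, cols + [1], same, "a")
        if j < len(b):
            pen = gap_extend if prev_gap == "b" else gap_open
            rec(i, j + 1, score - pen, cols + [1], same, "b")

    rec(0, 0, 0.0, [], 0, None)
    return best["score"], best["idents"]


class TestGlobalIdentity:
    def test_identical_sequences_are_100(self):
        assert global_identity("ACDEFGHIKL", "ACDEFGHIKL") == 100.0

    def test_one_substitution_in_ten(self):
        assert global_identity("ACDEFGHIKL", "ACDEFGHIKW") == pytest.approx(90.0)

    def test_invalid_symbols_listed(self):
        with pytest.raises(ParameterError, match="B.*Z|Z.*B"):
            global_identity("ABZ", "ACD")

    def test_matches_exhaustive_alignment_enumeration(self, rng):
        """Score (and identity, among co-optimal alignments) equal a
        brute-force enumeration over all global alignments of short words."""
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        mat = {
            x: {y: float(blosum[x, y]) for y in blosum.alphabet if y in "ACDEFGHIKLMNPQRSTVWY"}
            for x in blosum.alphabet
            if x in "ACDEFGHIKLMNPQRSTVWY"
        }
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(6):
            a = "".join(rng.choice(aas, rng.integers(3, 7)))
            b = "".join(rng.choice(aas, rng.integers(3, 7)))
            ident = global_identity(a, b, gap_open=10.0, gap_extend=0.5)
            # biopython gap model: first gap residue costs open, further extend
            score, idents = _enumerate_alignments(a, b, mat, 10.0, 0.5)
            assert any(ident == pytest.approx(v) for v in idents), (a, b, ident, idents)


class TestRepeatStats:
    def test_constant_lengths(self):
        segs = [DomainSegment(1 + 100 * i, 100 + 100 * i) for i in range(5)]
        st = repeat_stats(segs)
        assert st["count"] == 5
        assert st["length_mean"] == 100.0
        assert st["length_sd"] == 0.0

    def test_identical_sequences_give_100(self):
        from ciliacoat.repeats import StructureMSA

        segs = [DomainSegment(1, 4), DomainSegment(5, 8)]
        msa = StructureMSA(["ACDE", "ACDE"], segs, 0)
        assert repeat_stats(segs, msa)["mean_pairwise_identity"] == 100.0

    def test_synthetic_low_identity_set_near_target(self):
        model, bounds, _ = simulate_repeat_chain(RepeatChainSpec(k=8, seed=13))
        segs = [DomainSegment(a, b) for a, b in bounds]
        msa = structure_guided_msa(model, segs)
        st = repeat_stats(segs, msa)
        assert st["mean_pairwise_identity"] == pytest.approx(22.0, abs=3.0)

    def test_msa_identity_helper(self):
        assert msa_pairwise_identity("AC-E", "ACDE") == pytest.approx(75.0)
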