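"""ROH detection against an exhaustive oracle, F_L arithmetic, inbreeding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from herdsweep import (
    coverage_matrix,
    detect_roh,
    froh_per_animal,
    locus_autozygosity,
    pedigree_inbreeding,
)
from herdsweep.genotype_io import MISSING
from herdsweep.roh import mapped_lengths

from conftest import make_genotypes, make_map, make_pedigree


def brute_force_roh(codes, positions, min_snps, min_length_bp):
    """Exhaustive maximal-run scan over one animal's genotype string."""
    hom = [(c == 0 or c == 2) for c in codes]
    n = len(codes)
    out = []
    i = 0
    while i < n:
        if hom[i]:
            j = i
            while j + 1 < n and hom[j + 1]:
                j += 1
            n_snps = j - i + 1
            length = positions[j] - positions[i]
            if n_snps >= min_snps and length > min_length_bp:
                out.append((i, j, n_snps))
            i = j + 1
        else:
            i += 1
    return out


class TestDetectROH:
    def test_long_homozygous_run_reported(self):
        codes = np.full((1, 80), 1, dtype=np.int8)
        codes[0, 10:70] = 0  # 60 consecutive homozygous, spacing 50kb -> 2.95 Mb
        g = make_genotypes(codes)
        segs = detect_roh(g, min_snps=50, min_length_bp=1_000_000)
        assert len(segs) == 1
        assert segs[0].n_snps == 60
        assert segs[0].start_snp_index == 10 and segs[0].end_snp_index == 69

    def test_fully_heterozygous_animal_empty(self):
        g = make_genotypes(np.ones((1, 100), dtype=np.int8))
        assert detect_roh(g) == []

    def test_length_clause_enforced(self):
        # 55 homozygous SNPs spanning ~0.8 Mb (15 kb spacing): fails > 1 Mb
        codes = np.full((1, 55), 2, dtype=np.int8)
        g = make_genotypes(codes, spacing=15_000)
        assert detect_roh(g, min_snps=50, min_length_bp=1_000_000) == []
        # same run at 50 kb spacing spans 2.7 Mb: passes
        g2 = make_genotypes(codes, spacing=50_000)
        assert len(detect_roh(g2, min_snps=50, min_length_bp=1_000_000)) == 1

    def test_snp_count_clause_enforced(self):
        codes = np.full((1, 49), 0, dtype=np.int8)
        g = make_genotypes(codes, spacing=50_000)  # 2.4 Mb but only 49 SNPs
        assert detect_roh(g, min_snps=50, min_length_bp=1_000_000) == []

    def test_missing_breaks_by_default_but_bridges_with_skip(self):
        codes = np.full((1, 120), 0, dtype=np.int8)
        codes[0, 60] = MISSING
        g = make_genotypes(codes)
        broken = detect_roh(g, min_snps=50, min_length_bp=1_000_000)
        assert [s.n_snps for s in broken] == [60, 59]
        bridged = detect_roh(
            g, min_snps=50, min_length_bp=1_000_000, missing_policy="skip", bridge_k=1
        )
        assert len(bridged) == 1
        assert bridged[0].n_snps == 119  # missing call does not count

    def test_heterozygote_always_breaks_even_under_skip(self):
        codes = np.full((1, 120), 0, dtype=np.int8)
        codes[0, 60] = 1
        g = make_genotypes(codes)
        segs = detect_roh(
            g, min_snps=50, min_length_bp=1_000_000, missing_policy="skip", bridge_k=5
        )
        assert [s.n_snps for s in segs] == [60, 59]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_on_random_strings(self, seed):
        rng = np.random.default_rng(seed)
        codes = rng.choice(
            np.array([0, 1, 2, MISSING], dtype=np.int8),
            size=(1, 500),
            p=[0.45, 0.08, 0.45, 0.02],
        )
        g = make_genotypes(codes, spacing=30_000)
        segs = detect_roh(g, min_snps=20, min_length_bp=400_000)
        expected = brute_force_roh(
            codes[0].tolist(), g.markers.position_bp.tolist(), 20, 400_000
        )
        got = [(s.start_snp_index, s.end_snp_index, s.n_snps) for s in segs]
        assert got == expected

    def test_maximality(self, small_sim):
        segs = detect_roh(small_sim.genotypes, min_snps=10, min_length_bp=200_000)
        codes = small_sim.genotypes.codes
        row = {a: i for i, a in enumerate(small_sim.genotypes.animals)}
        markers = small_sim.genotypes.markers
        for s in segs[:200]:
            i = row[s.animal_id]
            for j in (s.start_snp_index - 1, s.end_snp_index + 1):
                if 0 <= j < codes.shape[1] and markers.chromosome[j] == s.chromosome:
                    assert codes[i, j] not in (0, 2)


class TestLocusAutozygosity:
    def test_direct_fraction(self):
        codes = np.ones((10, 60), dtype=np.int8)
        codes[:3] = 0  # 3 animals fully homozygous
        g = make_genotypes(codes)
        segs = detect_roh(g, min_snps=50, min_length_bp=1_000_000)
        track = locus_autozygosity(segs, g)
        assert np.allclose(track.fl, 0.3)

    def test_no_roh_gives_zero_everywhere(self):
        g = make_genotypes(np.ones((5, 60), dtype=np.int8))
        track = locus_autozygosity(detect_roh(g), g)
        assert np.all(track.fl == 0)

    def test_equals_column_mean_of_coverage(self, small_sim):
        g = small_sim.genotypes
        segs = detect_roh(g, min_snps=10, min_length_bp=200_000)
        track = locus_autozygosity(segs, g)
        cover = coverage_matrix(segs, g)
        assert np.array_equal(track.fl, cover.mean(axis=0))
        assert track.fl.min() >= 0 and track.fl.max() <= 1


class TestFroh:
    def test_extremes(self):
        codes = np.zeros((1, 60), dtype=np.int8)
        g = make_genotypes(codes)
        segs = detect_roh(g, min_snps=50, min_length_bp=1_000_000)
        out = froh_per_animal(segs, g.markers, g.animals)
        assert out["f_roh"].iloc[0] == 1.0
        het = make_genotypes(np.ones((1, 60), dtype=np.int8))
        out2 = froh_per_animal([], het.markers, het.animals)
        assert out2["f_roh"].iloc[0] == 0.0

    def test_matches_interval_union(self, small_sim):
        g = small_sim.genotypes
        segs = detect_roh(g, min_snps=10, min_length_bp=200_000)
        table = froh_per_animal(segs, g.markers, g.animals).set_index("animal_id")
        total = sum(mapped_lengths(g.markers).values())
        for animal in g.animals[:25]:
            ivals = [
                (s.start_bp, s.end_bp) for s in segs if s.animal_id == animal
            ]
            union = sum(e - s for s, e in ivals)  # segments never overlap per animal
            assert table.loc[animal, "f_roh"] == pytest.approx(union / total)


def recursive_kinship(parents):
    """Path-counting oracle: kinship via the standard recursion, memoised."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def phi(a, b):
        if a is None or b is None:
            return 0.0
        if a == b:
            s, d = parents.get(a, (None, None))
            return 0.5 * (1.0 + phi(s, d))
        # recurse on the younger (appears later in insertion order)
        order = list(parents)
        if order.index(a) < order.index(b):
            a, b = b, a
        s, d = parents.get(a, (None, None))
        return 0.5 * (phi(s, b) + phi(d, b))

    return phi


class TestPedigreeInbreeding:
    def test_closed_forms(self):
        ped = make_pedigree(
            [
                ("gs", None, None, 1980),
                ("gd", None, None, 1980),
                ("s", "gs", "gd", 1985),
                ("d", "gs", "gd", 1985),
                ("x_fullsib", "s", "d", 1990),
                ("gd2", None, None, 1980),
                ("s2", "gs", "gd2", 1985),
                ("x_halfsib", "s2", "d", 1990),
            ]
        )
        f = pedigree_inbreeding(ped).set_index("animal_id")["f_ped"]
        assert f["gs"] == 0.0
        assert f["x_fullsib"] == pytest.approx(0.25)
        assert f["x_halfsib"] == pytest.approx(0.125)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_recursive_oracle_on_random_pedigrees(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        ids = []
        for i in range(200):
            name = f"p{i}"
            if i < 20 or rng.random() < 0.1:
                rows.append((name, None, None, 1980 + i // 10))
            else:
                s = ids[rng.integers(0, len(ids))]
                d = ids[rng.integers(0, len(ids))]
                rows.append((name, s, d if d != s else None, 1980 + i // 10))
            ids.append(name)
        ped = make_pedigree(rows)
        table = pedigree_inbreeding(ped).set_index("animal_id")["f_ped"]
        parents = {r[0]: (r[1], r[2]) for r in rows}
        phi = recursive_kinship(parents)
        for name, (s, d) in list(parents.items())[::7]:
            # F = a(sire, dam)/2 and the additive relationship is twice the
            # kinship, so F equals the parents' kinship directly
            expected = phi(s, d) if (s and d) else 0.0
            assert table[name] == pytest.approx(expected, abs=1e-12)
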