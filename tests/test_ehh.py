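"""EHH decay, iHH integration, iHS standardisation, Rsb symmetry."""

import itertools

import numpy as np
import pytest

from herdsweep import (
    ehh,
    ihs_candidates,
    ihs_scan,
    integrate_ihh,
    rsb_candidates,
    rsb_scan,
    split_cohorts,
)
from herdsweep.ehh_stats import EHHCurve, EHHUndefined, _ies_site
from herdsweep.genotype_io import MISSING

from conftest import make_map, make_panel, make_pedigree


def brute_force_ehh(haps, positions, core, allele, offset_idx):
    """Pairwise identity oracle: fraction of carrier pairs identical from the
    core out to ``offset_idx`` (inclusive), by direct enumeration."""
    carriers = [h for h in haps if h[core] == str(allele)]
    lo, hi = sorted((core, offset_idx))
    pairs = list(itertools.combinations(carriers, 2))
    if not pairs:
        return float("nan")
    same = sum(1 for a, b in pairs if a[lo : hi + 1] == b[lo : hi + 1])
    return same / len(pairs)


class TestEHHCurve:
    def _panel_from_rows(self, rows, spacing=100_000):
        """rows: list of haplotype strings like '0110...' (one per haplotype)."""
        arr = np.array([[int(c) for c in r] for r in rows], dtype=np.int8)
        assert arr.shape[0] % 2 == 0
        haps = arr.reshape(arr.shape[0] // 2, 2, arr.shape[1])
        return make_panel(haps, spacing=spacing)

    def test_core_value_is_one_and_monotone(self):
        rng = np.random.default_rng(2)
        haps = rng.integers(0, 2, size=(10, 2, 40)).astype(np.int8)
        haps[:, :, 20] = 1  # everyone carries the core allele
        hp = make_panel(haps)
        curve = ehh(hp, 20, allele=1)
        for offs, vals in (curve.side("left"), curve.side("right")):
            assert vals[0] == 1.0
            assert np.all(np.diff(vals) <= 1e-12)

    def test_two_identical_pairs_give_one_third(self):
        rows = [
            "111",
            "111",
            "110",
            "110",
        ]
        hp = self._panel_from_rows(rows)
        curve = ehh(hp, 0, allele=1)
        # at the last SNP: two pairs identical out of C(4,2)=6
        offs, vals = curve.side("right")
        assert vals[-1] == pytest.approx(1 / 3)

    def test_identical_carriers_stay_at_one(self):
        rows = ["0101"] * 6
        hp = self._panel_from_rows(rows)
        curve = ehh(hp, 1, allele=1)
        assert np.all(curve.right_ehh == 1.0)
        assert np.all(curve.left_ehh == 1.0)

    def test_single_carrier_undefined(self):
        rows = ["100", "000", "000", "000"]
        hp = self._panel_from_rows(rows)
        with pytest.raises(EHHUndefined):
            ehh(hp, 0, allele=1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n_hap, L, core = 10, 15, 7
        arr = rng.integers(0, 2, size=(n_hap, L)).astype(np.int8)
        arr[: n_hap // 2, core] = 1
        arr[n_hap // 2 :, core] = 0
        hp = make_panel(arr.reshape(n_hap // 2, 2, L))
        curve = ehh(hp, core, allele=1)
        rows = ["".join(map(str, r)) for r in arr]
        for k, (offs, vals) in enumerate(
            (curve.side("left"), curve.side("right"))
        ):
            direction = -1 if k == 0 else 1
            for step in range(1, len(vals)):
                j = core + direction * step
                expected = brute_force_ehh(rows, None, core, 1, j)
                assert vals[step] == pytest.approx(expected), (direction, step)

    def test_missing_haplotype_leaves_risk_set(self):
        arr = np.array(
            [
                [1, 0, 0],
                [1, 0, 0],
                [1, MISSING, 0],
                [1, 1, 1],
            ],
            dtype=np.int8,
        )
        hp = make_panel(arr.reshape(2, 2, 3))
        curve = ehh(hp, 0, allele=1)
        # at SNP 1 the third haplotype is dropped: among the remaining 3,
        # one identical pair out of C(3,2)=3
        assert curve.right_ehh[1] == pytest.approx(1 / 3)


class TestIntegrateIHH:
    def _const_curve(self, value, span_bp, step_bp=100_000):
        offs = np.arange(0, span_bp + 1, step_bp, dtype=float)
        vals = np.full(len(offs), value)
        return EHHCurve(0, "x", offs, vals, offs.copy(), vals.copy())

    def test_rectangle(self):
        curve = self._const_curve(1.0, 2_000_000)
        assert integrate_ihh(curve) == pytest.approx(4_000_000.0)

    def test_truncation_excludes_tail(self):
        offs = np.array([0.0, 1e5, 2e5, 3e5])
        vals = np.array([1.0, 0.5, 0.01, 0.5])
        curve = EHHCurve(0, "x", np.array([0.0]), np.array([1.0]), offs, vals)
        # right side integrates only [0, 1e5] -> trapezoid 0.75 * 1e5
        assert integrate_ihh(curve, truncation_ehh=0.05) == pytest.approx(75_000.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_fine_grid_riemann(self, seed):
        rng = np.random.default_rng(seed)
        offs = np.sort(rng.uniform(0, 1e6, size=30))
        offs[0] = 0.0
        vals = np.sort(rng.uniform(0.1, 1.0, size=30))[::-1]
        vals[0] = 1.0
        curve = EHHCurve(0, "x", offs, vals, np.array([0.0]), np.array([1.0]))
        # piecewise-linear fine-grid Riemann sum oracle
        grid = np.linspace(0, offs[-1], 200_001)
        riemann = np.sum(np.interp(grid, offs, vals)) * (offs[-1] / 200_000)
        assert integrate_ihh(curve, truncation_ehh=0.0) == pytest.approx(
            riemann, rel=1e-4
        )


@pytest.fixture(scope="module")
def neutral_panel():
    from herdsweep.synthetic_data import SimConfig, simulate_breeding

    cfg = SimConfig(
        n_chromosomes=2,
        snps_per_chromosome=250,
        chromosome_length_bp=25_000_000,
        n_ancestral_haplotypes=12,
        year_start=1980,
        year_end=2007,
        animals_per_year=15,
        n_founders=30,
        n_sires_per_year=3,
        sire_selection_fraction=0.5,
        rng_seed=21,
    )
    return simulate_breeding(cfg)


class TestIHS:
    def test_equal_ihh_gives_zero_unstandardized(self):
        rng = np.random.default_rng(4)
        # symmetric panel: derived and ancestral carriers have mirrored haplotypes
        block = rng.integers(0, 2, size=(6, 21)).astype(np.int8)
        arr = np.vstack([block, block])
        core = 10
        arr[:6, core] = 0
        arr[6:, core] = 1
        hp = make_panel(arr.reshape(6, 2, 21))
        hp.markers.ancestral[:] = 0
        df = ihs_scan(hp, maf_min=0.0, n_bins=1)
        assert df["unstandardized"].iloc[core] == pytest.approx(0.0, abs=1e-12)

    def test_bins_standardized_to_mean_zero_var_one(self, neutral_panel):
        hp = neutral_panel.haplotypes
        df = ihs_scan(hp, maf_min=0.03, n_bins=20)
        usable = df["ihs"].notna()
        assert usable.sum() > 100
        for b, grp in df[usable].groupby("freq_bin"):
            if len(grp) < 10:
                continue
            assert abs(grp["ihs"].mean()) < 1e-9
            assert grp["ihs"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_neutral_tail_fraction_reasonable(self, neutral_panel):
        df = ihs_scan(neutral_panel.haplotypes, maf_min=0.03)
        vals = df["ihs"].dropna()
        frac = float((vals.abs() > 2).mean())
        # two-sided normal tail is ~0.0455; allow +-50% relative
        assert 0.5 * 0.0455 < frac < 1.5 * 0.0455 or vals.size < 500


class TestIHSCandidates:
    def _frame(self, pos, ihs_vals, chrom=1):
        import pandas as pd

        return pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(len(pos))],
                "chromosome": chrom,
                "position_bp": pos,
                "ihs": ihs_vals,
            }
        )

    def test_isolated_peak_not_retained(self):
        pos = np.arange(0, 2_000_000, 100_000)
        vals = np.zeros(len(pos))
        vals[10] = 3.5
        assert ihs_candidates(self._frame(pos, vals)) == []

    def test_supported_peak_retained(self):
        pos = np.arange(0, 2_100_000, 50_000)
        vals = np.zeros(len(pos))
        centre = 21
        vals[centre] = 3.2
        support = [centre + d for d in range(-6, 7) if d != 0]
        for s in support:
            vals[s] = 2.5  # 12 supports within 0.3 Mb
        regions = ihs_candidates(self._frame(pos, vals))
        assert len(regions) == 1
        assert regions[0].peak_statistic == pytest.approx(3.2)

    @pytest.mark.parametrize("seed", range(4))
    def test_filter_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(np.arange(0, 10_000_000, 10_000), 300, replace=False)).astype(float)
        vals = rng.normal(0, 1.6, size=300)
        df = self._frame(pos, vals)
        regions = ihs_candidates(df)
        retained_in_regions = set()
        for r in regions:
            for i in range(300):
                if (
                    r.start_bp <= pos[i] <= r.end_bp
                    and abs(vals[i]) > 3.0
                ):
                    retained_in_regions.add(i)
        # oracle: all-pairs distance check
        oracle = set()
        for i in range(300):
            if abs(vals[i]) > 3.0:
                n_support = sum(
                    1
                    for j in range(300)
                    if j != i
                    and abs(pos[j] - pos[i]) <= 500_000
                    and abs(vals[j]) > 2.0
                )
                if n_support >= 10:
                    oracle.add(i)
        # every oracle-retained core must fall inside a region and vice versa
        assert oracle == {
            i
            for i in retained_in_regions
            if sum(
                1
                for j in range(300)
                if j != i
                and abs(pos[j] - pos[i]) <= 500_000
                and abs(vals[j]) > 2.0
            )
            >= 10
        }
        if not oracle:
            assert regions == []


class TestCohortsAndRsb:
    def _pedigree_for(self, animals, years):
        return make_pedigree(
            [(a, None, None, int(y)) for a, y in zip(animals, years)]
        )

    def test_split_sizes_and_determinism(self):
        animals = [f"an{i}" for i in range(120)]
        years = np.r_[np.linspace(1960, 1990, 50).astype(int), np.full(70, 2004)]
        ped = self._pedigree_for(animals, years)
        s1 = split_cohorts(ped, animals, n_ancestral=40, rng_seed=5)
        s2 = split_cohorts(ped, animals, n_ancestral=40, rng_seed=5)
        assert s1.ancestral == s2.ancestral and s1.contemporary == s2.contemporary
        assert len(s1.ancestral) == len(s1.contemporary) == 40
        assert not set(s1.ancestral) & set(s1.contemporary)

    def test_split_insufficient_raises(self):
        animals = [f"an{i}" for i in range(20)]
        ped = self._pedigree_for(animals, [1985] * 10 + [2004] * 10)
        with pytest.raises(ValueError, match="born before"):
            split_cohorts(ped, animals, n_ancestral=15)

    def _sim_panel(self, seed=0):
        rng = np.random.default_rng(seed)
        haps = rng.integers(0, 2, size=(40, 2, 60)).astype(np.int8)
        return make_panel(haps, spacing=100_000)

    def test_identical_cohorts_give_zero_ln_ratio(self):
        hp = self._sim_panel()
        # contemporary animals are exact copies of ancestral animals
        hp.haps[20:] = hp.haps[:20]
        split_obj = _manual_split(hp, 20)
        df = rsb_scan(hp, split_obj, maf_min=0.0)
        usable = df["ln_ratio"].dropna()
        assert len(usable) > 0
        assert np.allclose(usable, 0.0)

    def test_group_swap_negates_ln_ratio(self):
        hp = self._sim_panel(seed=9)
        s = _manual_split(hp, 20)
        swapped = type(s)(
            ancestral=s.contemporary,
            contemporary=s.ancestral,
            ancestral_cutoff_year=s.ancestral_cutoff_year,
            contemporary_years=s.contemporary_years,
            rng_seed=s.rng_seed,
        )
        a = rsb_scan(hp, s, maf_min=0.0)["ln_ratio"]
        b = rsb_scan(hp, swapped, maf_min=0.0)["ln_ratio"]
        mask = a.notna() & b.notna()
        assert mask.any()
        assert np.allclose(a[mask], -b[mask], atol=1e-12)


def _manual_split(hp, n_half):
    from herdsweep.ehh_stats import CohortSplit

    return CohortSplit(
        ancestral=hp.animals[:n_half],
        contemporary=hp.animals[n_half : 2 * n_half],
        ancestral_cutoff_year=1991,
        contemporary_years=(2001, 2007),
        rng_seed=0,
    )


class TestRsbCandidates:
    def _frame(self, pos, vals, chrom=1):
        import pandas as pd

        return pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(len(pos))],
                "chromosome": chrom,
                "position_bp": pos,
                "rsb": vals,
            }
        )

    def test_no_peak_means_no_region(self):
        pos = np.arange(0, 200_000, 5_000)  # 40 SNPs in 200 kb
        vals = np.full(len(pos), 2.5)  # 25+ SNPs >= 2 but none >= 3
        assert rsb_candidates(self._frame(pos, vals)) == []

    def test_window_with_peak_retained(self):
        pos = np.arange(0, 200_000, 5_000)
        vals = np.full(len(pos), 2.5)
        vals[10] = 3.4
        regions = rsb_candidates(self._frame(pos, vals))
        assert len(regions) == 1
        assert regions[0].peak_statistic == pytest.approx(3.4)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(np.arange(0, 3_000_000, 4_000), 400, replace=False)).astype(float)
        vals = rng.normal(0, 1.8, size=400)
        regions = rsb_candidates(self._frame(pos, vals))
        # oracle: enumerate every window start, mark SNPs in retained windows
        flagged = np.zeros(400, dtype=bool)
        for i in range(400):
            inside = (pos >= pos[i]) & (pos <= pos[i] + 200_000)
            if (np.abs(vals[inside]) >= 2).sum() >= 20 and (
                np.abs(vals[inside]) >= 3
            ).any():
                flagged |= inside
        from_regions = np.zeros(400, dtype=bool)
        for r in regions:
            from_regions |= (pos >= r.start_bp) & (pos <= r.end_bp)
        assert np.array_equal(flagged, from_regions)
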