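"""Extended haplotype homozygosity: EHH/iHH/iHS and cross-cohort EHHS/iES/Rsb.

EHH at offset x from a core SNP is the probability that two randomly drawn
carrier haplotypes are identical over the whole stretch from the core to x:
EHH(x) = sum_h C(n_h, 2) / C(n, 2) over the distinct extended haplotypes h
among the n carriers.  iHH is the area under the EHH decay curve against
physical distance (trapezoid rule), truncated where EHH falls below a cutoff
(default 0.05) or at the bracket edge (default 5 Mb), whichever comes first.

iHS is the per-core ln(iHH_ancestral / iHH_derived), standardised to mean 0
and variance 1 within derived-allele-frequency bins, so that extreme values
are comparable across frequencies.

For the cohort contrast, site-EHH (EHHS) is computed over ALL haplotypes of a
group anchored at the SNP irrespective of allele; its integral is iES.  Rsb
is ln(iES_ancestral / iES_contemporary) standardised genome-wide: it is
antisymmetric under swapping the two groups and identically zero when the
groups carry identical haplotypes.

Integration is over physical distance (bp): the array provides no genetic
map, and brackets are framed in Mb.  If two adjacent scored SNPs are more
than ``gap_bp`` apart (default 500 kb), integration stops at the gap, a guard
against assembly gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, HaplotypePanel, MarkerMap, PedigreeTable
from .selection_scan import CandidateRegion

DEFAULT_BRACKET_BP = 5_000_000
DEFAULT_TRUNCATION_EHH = 0.05
DEFAULT_GAP_BP = 500_000


@dataclass
class EHHCurve:
    core_snp_index: int  # index within the chromosome arrays passed in
    label: str  # "ancestral" / "derived" / "all" (EHHS)
    left_offsets_bp: np.ndarray  # distances (bp, >= 0) walking left from the core
    left_ehh: np.ndarray
    right_offsets_bp: np.ndarray  # positive distances from the core, starting at 0
    right_ehh: np.ndarray

    def side(self, direction: str) -> tuple[np.ndarray, np.ndarray]:
        if direction == "left":
            return self.left_offsets_bp, self.left_ehh
        if direction == "right":
            return self.right_offsets_bp, self.right_ehh
        raise ValueError("direction must be 'left' or 'right'")


class EHHUndefined(ValueError):
    """Core allele carried by fewer than two haplotypes."""


def _pairwise_hom(counts: np.ndarray, n: int) -> float:
    """sum C(c,2) / C(n,2)."""
    if n < 2:
        return float("nan")
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def _ehh_side(
    H: np.ndarray,
    pos: np.ndarray,
    core: int,
    rows: np.ndarray,
    direction: int,
    max_bracket_bp: float,
    gap_bp: float,
    stop_below: float,
) -> tuple[np.ndarray, np.ndarray]:
    """EHH values walking outward from ``core`` in ``direction`` (+1 right / -1 left).

    ``rows`` indexes the carrier haplotypes (for EHHS: all haplotypes of the
    group, regardless of the core allele).  Haplotypes leave
    the risk set at the first missing allele; EHH is then computed among the
    remaining n.  Returns (distances_bp >= 0, ehh values), both starting at
    the core (distance 0, EHH 1).
    """
    n0 = rows.size
    offsets = [0.0]
    values = [1.0]
    labels = np.zeros(n0, dtype=np.int64)
    n_labels = 1
    alive = np.ones(n0, dtype=bool)
    j = core
    last_pos = pos[core]
    L = len(pos)
    while True:
        j += direction
        if j < 0 or j >= L:
            break
        dist = abs(int(pos[j]) - int(pos[core]))
        if dist > max_bracket_bp:
            break
        if abs(int(pos[j]) - int(last_pos)) > gap_bp:
            break
        col = H[rows, j]
        alive &= col != MISSING
        n = int(alive.sum())
        if n < 2:
            break
        # split each group by the new allele, then compact the label space
        # with a bincount (O(n), no sort)
        key = labels[alive] * 2 + col[alive]
        cnt = np.bincount(key, minlength=2 * n_labels)
        mapping = np.cumsum(cnt > 0) - 1
        labels[alive] = mapping[key]
        counts = cnt[cnt > 0]
        n_labels = counts.size
        ehh = _pairwise_hom(counts, n)
        offsets.append(float(dist))
        values.append(ehh)
        last_pos = pos[j]
        if ehh < stop_below:
            break
    return np.array(offsets), np.array(values)


def ehh(
    hp_or_matrix,
    core_snp_index: int,
    allele: int | None,
    max_bracket_bp: float = DEFAULT_BRACKET_BP,
    gap_bp: float = DEFAULT_GAP_BP,
    positions: np.ndarray | None = None,
) -> EHHCurve:
    """EHH decay curve around a core SNP for carriers of ``allele``.

    ``hp_or_matrix`` is a HaplotypePanel (the core index is then a flat panel
    index and the chromosome is inferred) or a raw (n_haplotypes, L) matrix
    with explicit ``positions``.  ``allele=None`` computes site-EHH (EHHS)
    over all haplotypes.  The curve is computed to the bracket edge; apply
    the truncation rule at integration time.
    """
    H, pos, core = _resolve(hp_or_matrix, core_snp_index, positions)
    if allele is None:
        rows = np.flatnonzero(H[:, core] != MISSING)
        label = "all"
    else:
        rows = np.flatnonzero(H[:, core] == allele)
        label = f"allele{allele}"
    if rows.size < 2:
        raise EHHUndefined(
            f"core SNP {core_snp_index}: allele carried by {rows.size} haplotype(s)"
        )
    lo, lv = _ehh_side(H, pos, core, rows, -1, max_bracket_bp, gap_bp, 0.0)
    ro, rv = _ehh_side(H, pos, core, rows, +1, max_bracket_bp, gap_bp, 0.0)
    return EHHCurve(core, label, lo, lv, ro, rv)


def _resolve(hp_or_matrix, core: int, positions):
    if isinstance(hp_or_matrix, HaplotypePanel):
        markers = hp_or_matrix.markers
        chrom = int(markers.chromosome[core])
        sl = markers.chrom_slice(chrom)
        H = hp_or_matrix.hap_matrix()[:, sl]
        return H, markers.position_bp[sl], core - sl.start
    if positions is None:
        raise ValueError("positions required with a raw haplotype matrix")
    return np.asarray(hp_or_matrix), np.asarray(positions), core


def integrate_ihh(
    curve: EHHCurve, truncation_ehh: float = DEFAULT_TRUNCATION_EHH
) -> float:
    """Trapezoidal area under the EHH curve, both sides summed (bp x EHH units).

    Each side is truncated at the first point where EHH < ``truncation_ehh``
    (that point is excluded) or at the bracket edge, whichever comes first.
    """
    total = 0.0
    for offs, vals in ((curve.left_offsets_bp, curve.left_ehh), (curve.right_offsets_bp, curve.right_ehh)):
        below = np.flatnonzero(vals < truncation_ehh)
        stop = below[0] if below.size else len(vals)
        if stop >= 2:
            total += float(np.trapezoid(vals[:stop], offs[:stop]))
    return total


def _ihh_site(
    H: np.ndarray,
    pos: np.ndarray,
    core: int,
    rows: np.ndarray,
    max_bracket_bp: float,
    gap_bp: float,
    truncation_ehh: float,
) -> float:
    """Fused EHH walk + trapezoid integral for one core and carrier set."""
    total = 0.0
    for direction in (-1, +1):
        offs, vals = _ehh_side(
            H, pos, core, rows, direction, max_bracket_bp, gap_bp, truncation_ehh
        )
        below = np.flatnonzero(vals < truncation_ehh)
        stop = below[0] if below.size else len(vals)
        if stop >= 2:
            total += float(np.trapezoid(vals[:stop], offs[:stop]))
    return total


# ---------------------------------------------------------------------------
# iHS
# ---------------------------------------------------------------------------


def ihs_scan(
    hp: HaplotypePanel,
    maf_min: float = 0.03,
    n_bins: int = 20,
    max_bracket_bp: float = DEFAULT_BRACKET_BP,
    truncation_ehh: float = DEFAULT_TRUNCATION_EHH,
    gap_bp: float = DEFAULT_GAP_BP,
    min_bin_count: int = 2,
) -> pd.DataFrame:
    """Standardised iHS per core SNP.

    Cores require a known ancestral allele and MAF >= ``maf_min``.  The raw
    statistic is ln(iHH_ancestral / iHH_derived); standardisation subtracts
    the mean and divides by the s.d. (ddof=1) within ``n_bins`` equal-width
    derived-allele-frequency bins over [0, 1].  Cores whose iHH is undefined
    (fewer than two carriers of either allele) or whose bin holds fewer than
    ``min_bin_count`` scored cores are flagged and left unstandardised.
    """
    markers = hp.markers
    freq_b = hp.allele_b_frequency()
    maf = np.minimum(freq_b, 1 - freq_b)
    anc = markers.ancestral
    out = {
        "snp_id": markers.snp_id,
        "chromosome": markers.chromosome,
        "position_bp": markers.position_bp,
        "derived_freq": np.where(anc == 0, freq_b, 1 - freq_b),
        "ihh_ancestral": np.full(markers.n_snps, np.nan),
        "ihh_derived": np.full(markers.n_snps, np.nan),
        "unstandardized": np.full(markers.n_snps, np.nan),
        "flag": np.array([""] * markers.n_snps, dtype=object),
    }
    scored = (anc != MISSING) & (np.nan_to_num(maf) >= maf_min)
    Hfull = hp.hap_matrix()
    for chrom in markers.chromosomes():
        sl = markers.chrom_slice(int(chrom))
        H = Hfull[:, sl]
        pos = markers.position_bp[sl]
        for core_local in np.flatnonzero(scored[sl]):
            j = sl.start + core_local
            a = int(anc[j])
            d = 1 - a
            rows_a = np.flatnonzero(H[:, core_local] == a)
            rows_d = np.flatnonzero(H[:, core_local] == d)
            if rows_a.size < 2 or rows_d.size < 2:
                out["flag"][j] = "lowcount"
                continue
            iha = _ihh_site(H, pos, core_local, rows_a, max_bracket_bp, gap_bp, truncation_ehh)
            ihd = _ihh_site(H, pos, core_local, rows_d, max_bracket_bp, gap_bp, truncation_ehh)
            out["ihh_ancestral"][j] = iha
            out["ihh_derived"][j] = ihd
            if iha <= 0 or ihd <= 0:
                out["flag"][j] = "zero_ihh"
                continue
            out["unstandardized"][j] = np.log(iha / ihd)
    df = pd.DataFrame(out)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    df["freq_bin"] = np.clip(
        np.digitize(df["derived_freq"], edges[1:-1]), 0, n_bins - 1
    )
    df["ihs"] = np.nan
    usable = df["unstandardized"].notna()
    for b, grp in df[usable].groupby("freq_bin"):
        if len(grp) < min_bin_count or grp["unstandardized"].std(ddof=1) == 0:
            df.loc[grp.index, "flag"] = "thin_bin"
            continue
        mu = grp["unstandardized"].mean()
        sd = grp["unstandardized"].std(ddof=1)
        df.loc[grp.index, "ihs"] = (grp["unstandardized"] - mu) / sd
    return df


def ihs_candidates(
    ihs: pd.DataFrame,
    core_threshold: float = 3.0,
    support_threshold: float = 2.0,
    support_radius_bp: float = 500_000,
    min_support: int = 10,
    merge_gap_bp: float = 1_000_000,
) -> list[CandidateRegion]:
    """False-positive filter and region grouping for the iHS scan.

    A core is retained when |iHS| > ``core_threshold`` and at least
    ``min_support`` *other* scored SNPs within ``support_radius_bp`` have
    |iHS| > ``support_threshold``.  Retained cores and their supporting SNPs
    are merged into regions; retained cores closer than ``merge_gap_bp``
    share a region.
    """
    df = ihs.dropna(subset=["ihs"]).reset_index(drop=True)
    regions: list[CandidateRegion] = []
    for chrom, sub in df.groupby("chromosome", sort=True):
        sub = sub.sort_values("position_bp").reset_index(drop=True)
        pos = sub["position_bp"].to_numpy(float)
        val = sub["ihs"].abs().to_numpy()
        support = val > support_threshold
        retained = []
        for i in np.flatnonzero(val > core_threshold):
            near = (np.abs(pos - pos[i]) <= support_radius_bp) & support
            near[i] = False
            if near.sum() >= min_support:
                retained.append(i)
        if not retained:
            continue
        groups: list[list[int]] = [[retained[0]]]
        for i in retained[1:]:
            if pos[i] - pos[groups[-1][-1]] <= merge_gap_bp:
                groups[-1].append(i)
            else:
                groups.append([i])
        for grp in groups:
            lo_core, hi_core = pos[grp[0]], pos[grp[-1]]
            in_region = (pos >= lo_core - support_radius_bp) & (
                pos <= hi_core + support_radius_bp
            ) & (val > support_threshold)
            member_pos = pos[in_region]
            start, end = float(member_pos.min()), float(member_pos.max())
            inside = (pos >= start) & (pos <= end)
            peak = int(np.argmax(np.where(inside, val, -np.inf)))
            regions.append(
                CandidateRegion(
                    chromosome=int(chrom),
                    start_bp=int(start),
                    end_bp=int(end),
                    peak_statistic=float(val[peak]),
                    peak_position_bp=int(pos[peak]),
                    n_snps=int((val[inside] > support_threshold).sum()),
                    direction=float(np.sign(sub["ihs"].to_numpy()[peak])),
                    rule_id="ihs_filter",
                )
            )
    return regions


# ---------------------------------------------------------------------------
# cohorts and Rsb
# ---------------------------------------------------------------------------


@dataclass
class CohortSplit:
    ancestral: list[str]
    contemporary: list[str]
    ancestral_cutoff_year: int
    contemporary_years: tuple[int, int]
    rng_seed: int

    def __post_init__(self) -> None:
        if set(self.ancestral) & set(self.contemporary):
            raise ValueError("cohorts must be disjoint")
        if len(self.ancestral) != len(self.contemporary):
            raise ValueError("cohorts must be equal-sized")


def split_cohorts(
    ped: PedigreeTable,
    genotyped_animals: list[str],
    n_ancestral: int = 300,
    ancestral_cutoff_year: int = 1991,
    contemporary_years: tuple[int, int] = (2001, 2007),
    rng_seed: int = 0,
) -> CohortSplit:
    """Oldest-versus-recent cohort split among genotyped animals.

    Ancestral: the ``n_ancestral`` oldest animals born before the cutoff
    (ties broken by animal id for determinism).  Contemporary: a seeded
    uniform sample of equal size from the stated recent birth-year window.
    """
    years = ped.birth_years(genotyped_animals)
    old = [
        (years[i], genotyped_animals[i])
        for i in range(len(genotyped_animals))
        if not np.isnan(years[i]) and years[i] < ancestral_cutoff_year
    ]
    if len(old) < n_ancestral:
        raise ValueError(
            f"only {len(old)} animals born before {ancestral_cutoff_year}; "
            f"{n_ancestral} requested"
        )
    old.sort(key=lambda t: (t[0], t[1]))
    ancestral = [a for _, a in old[:n_ancestral]]
    lo, hi = contemporary_years
    recent = [
        genotyped_animals[i]
        for i in range(len(genotyped_animals))
        if not np.isnan(years[i]) and lo <= years[i] <= hi
    ]
    recent = [a for a in recent if a not in set(ancestral)]
    if len(recent) < n_ancestral:
        raise ValueError(
            f"only {len(recent)} animals born {lo}-{hi}; {n_ancestral} needed"
        )
    rng = np.random.default_rng(rng_seed)
    contemporary = sorted(rng.choice(recent, size=n_ancestral, replace=False).tolist())
    return CohortSplit(ancestral, contemporary, ancestral_cutoff_year, contemporary_years, rng_seed)


def rsb_scan(
    hp: HaplotypePanel,
    split: CohortSplit,
    maf_min: float = 0.02,
    max_bracket_bp: float = DEFAULT_BRACKET_BP,
    truncation_ehh: float = DEFAULT_TRUNCATION_EHH,
    gap_bp: float = DEFAULT_GAP_BP,
) -> pd.DataFrame:
    """Standardised Rsb per SNP between the ancestral and contemporary cohorts.

    Per scored SNP (pooled MAF >= ``maf_min``), site-EHH (EHHS, over all
    haplotypes of a group, anchored at the SNP irrespective of allele) is
    integrated to iES in each group; the raw statistic is
    ln(iES_ancestral / iES_contemporary), standardised genome-wide (single
    bin) to mean 0, variance 1.
    """
    markers = hp.markers
    row_of = {a: i for i, a in enumerate(hp.animals)}
    idx_a = np.array([row_of[a] for a in split.ancestral])
    idx_c = np.array([row_of[a] for a in split.contemporary])
    Hfull = hp.hap_matrix()
    hap_rows = lambda idx: np.concatenate([2 * idx, 2 * idx + 1])
    rows_a, rows_c = hap_rows(idx_a), hap_rows(idx_c)
    freq_b = hp.allele_b_frequency()
    maf = np.minimum(freq_b, 1 - freq_b)
    scored = np.nan_to_num(maf) >= maf_min
    n = markers.n_snps
    ies_a = np.full(n, np.nan)
    ies_c = np.full(n, np.nan)
    flag = np.array([""] * n, dtype=object)
    for chrom in markers.chromosomes():
        sl = markers.chrom_slice(int(chrom))
        pos = markers.position_bp[sl]
        Ha = Hfull[np.ix_(rows_a, np.arange(sl.start, sl.stop))]
        Hc = Hfull[np.ix_(rows_c, np.arange(sl.start, sl.stop))]
        for core_local in np.flatnonzero(scored[sl]):
            j = sl.start + core_local
            va = _ies_site(Ha, pos, core_local, max_bracket_bp, gap_bp, truncation_ehh)
            vc = _ies_site(Hc, pos, core_local, max_bracket_bp, gap_bp, truncation_ehh)
            ies_a[j], ies_c[j] = va, vc
            if not (va > 0 and vc > 0):
                flag[j] = "zero_ies"
    with np.errstate(invalid="ignore", divide="ignore"):
        ln_ratio = np.where((ies_a > 0) & (ies_c > 0), np.log(ies_a / ies_c), np.nan)
    usable = ~np.isnan(ln_ratio)
    rsb = np.full(n, np.nan)
    if usable.sum() >= 2:
        mu = ln_ratio[usable].mean()
        sd = ln_ratio[usable].std(ddof=1)
        if sd > 0:
            rsb[usable] = (ln_ratio[usable] - mu) / sd
    return pd.DataFrame(
        {
            "snp_id": markers.snp_id,
            "chromosome": markers.chromosome,
            "position_bp": markers.position_bp,
            "ies_ancestral": ies_a,
            "ies_contemporary": ies_c,
            "ln_ratio": ln_ratio,
            "rsb": rsb,
            "flag": flag,
        }
    )


def _ies_site(H, pos, core, max_bracket_bp, gap_bp, truncation_ehh) -> float:
    rows = np.flatnonzero(H[:, core] != MISSING)
    if rows.size < 2:
        return float("nan")
    total = 0.0
    for direction in (-1, +1):
        offs, vals = _ehh_side(
            H, pos, core, rows, direction, max_bracket_bp, gap_bp, truncation_ehh
        )
        below = np.flatnonzero(vals < truncation_ehh)
        stop = below[0] if below.size else len(vals)
        if stop >= 2:
            total += float(np.trapezoid(vals[:stop], offs[:stop]))
    return total


def rsb_candidates(
    rsb: pd.DataFrame,
    window_bp: float = 200_000,
    min_count: int = 20,
    count_threshold: float = 2.0,
    peak_threshold: float = 3.0,
) -> list[CandidateRegion]:
    """Sliding-window grouping of extreme Rsb loci.

    Every SNP position opens a window [pos, pos + window_bp]; a window is
    retained when it holds >= ``min_count`` SNPs with |Rsb| >= 2 of which at
    least one has |Rsb| >= 3.  Overlapping retained windows are merged.
    """
    df = rsb.dropna(subset=["rsb"])
    regions: list[CandidateRegion] = []
    for chrom, sub in df.groupby("chromosome", sort=True):
        sub = sub.sort_values("position_bp")
        pos = sub["position_bp"].to_numpy(float)
        val = sub["rsb"].abs().to_numpy()
        raw = sub["rsb"].to_numpy()
        kept: list[tuple[float, float]] = []
        for i in range(len(pos)):
            inside = (pos >= pos[i]) & (pos <= pos[i] + window_bp)
            if (val[inside] >= count_threshold).sum() >= min_count and (
                val[inside] >= peak_threshold
            ).any():
                kept.append((pos[i], pos[i] + window_bp))
        if not kept:
            continue
        merged = [list(kept[0])]
        for lo, hi in kept[1:]:
            if lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        for lo, hi in merged:
            inside = (pos >= lo) & (pos <= hi)
            peak = int(np.argmax(np.where(inside, val, -np.inf)))
            regions.append(
                CandidateRegion(
                    chromosome=int(chrom),
                    start_bp=int(lo),
                    end_bp=int(hi),
                    peak_statistic=float(val[peak]),
                    peak_position_bp=int(pos[peak]),
                    n_snps=int((val[inside] >= count_threshold).sum()),
                    direction=float(np.sign(raw[peak])),
                    rule_id="rsb_windows",
                )
            )
    return regions


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
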