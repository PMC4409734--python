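"""Sliding 50-SNP haplotype windows: frequency catalogues, birth-year trends,
and additive trait (PTA) associations of the most frequent haplotype.

For each window the phased haplotypes are catalogued by exact string identity
(no mismatch tolerance).  The most frequent haplotype is the analysis unit:

* birth-year scan — carriage of the top haplotype (G >= 1) is regressed on
  birth year with the same vectorised logistic machinery and permutation
  thresholds as the per-SNP autozygosity scan;
* trait association — the additive model y = mu + beta * G + e is fitted by
  least squares per window, with G the animal's copy count (0/1/2) of the top
  haplotype and every other haplotype's effect set to 0; the experiment-wise
  threshold comes from permuting trait values across animals.

Animals with a missing phased allele anywhere in a window are dropped from
that window's catalogue (haplotype strings must be complete).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, HaplotypePanel, PedigreeTable, TraitTable
from .selection_scan import (
    LogisticScanResult,
    PermutationThresholds,
    logistic_scan,
    permutation_thresholds,
)


@dataclass
class HaplotypeWindow:
    window_id: str
    chromosome: int
    start_snp_index: int  # flat panel index of the first SNP
    snp_count: int
    catalogue: pd.DataFrame  # columns haplotype (string), count
    top_haplotype: str
    top_frequency: float  # among complete haplotypes in the window
    tie: bool  # True if another haplotype matched the top count
    copies: np.ndarray  # per animal: G in {0,1,2}, MISSING if dropped
    start_bp: int = 0
    end_bp: int = 0

    @property
    def mid_bp(self) -> int:
        return (self.start_bp + self.end_bp) // 2


@dataclass
class TraitAssocResult:
    trait: str
    window_ids: list[str]
    mu: np.ndarray
    beta: np.ndarray  # trait units per top-haplotype copy
    p_value: np.ndarray
    neg_log10_p: np.ndarray
    estimable: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_id": self.window_ids,
                "trait": self.trait,
                "mu": self.mu,
                "beta": self.beta,
                "p_value": self.p_value,
                "neg_log10_p": self.neg_log10_p,
                "estimable": self.estimable,
            }
        )


# ---------------------------------------------------------------------------
# window enumeration
# ---------------------------------------------------------------------------


def enumerate_windows(
    hp: HaplotypePanel, window_snps: int = 50, step_snps: int = 1
) -> list[HaplotypeWindow]:
    """Catalogue haplotypes in sliding windows that never span chromosomes.

    Ties for the most frequent haplotype are broken lexicographically
    (smallest allele string wins) and flagged.  Chromosomes shorter than the
    window produce no windows.
    """
    markers = hp.markers
    n_animals = hp.n_animals
    windows: list[HaplotypeWindow] = []
    for chrom in markers.chromosomes():
        sl = markers.chrom_slice(int(chrom))
        n = sl.stop - sl.start
        if n < window_snps:
            continue
        for start in range(0, n - window_snps + 1, step_snps):
            lo = sl.start + start
            hi = lo + window_snps
            block = hp.haps[:, :, lo:hi]  # (n_animals, 2, w)
            complete = ~np.any(block == MISSING, axis=2)  # (n_animals, 2)
            animal_ok = complete.all(axis=1)
            rows = block[animal_ok].reshape(-1, window_snps)
            if rows.shape[0] == 0:
                continue
            # byte-view unique: rows hold only 0/1, so bytewise order equals
            # lexicographic row order (and is much faster than axis=0 unique)
            void = np.ascontiguousarray(rows).view(
                np.dtype((np.void, window_snps))
            )[:, 0]
            uniq_v, inverse, counts = np.unique(
                void, return_inverse=True, return_counts=True
            )
            uniq = uniq_v.view(np.int8).reshape(-1, window_snps)
            # np.unique sorts rows lexicographically, so among tied counts the
            # first argmax is the lexicographically smallest haplotype
            top = int(np.argmax(counts))
            tie = int(np.sum(counts == counts[top])) > 1
            top_row = uniq[top]
            copies = np.full(n_animals, MISSING, dtype=np.int8)
            hap_is_top = (inverse == top).reshape(-1, 2)
            copies[animal_ok] = hap_is_top.sum(axis=1).astype(np.int8)
            hap_str = ["".join(map(str, row)) for row in uniq]
            windows.append(
                HaplotypeWindow(
                    window_id=f"chr{chrom}_w{start}",
                    chromosome=int(chrom),
                    start_snp_index=lo,
                    snp_count=window_snps,
                    catalogue=pd.DataFrame({"haplotype": hap_str, "count": counts}),
                    top_haplotype=hap_str[top],
                    top_frequency=float(counts[top] / rows.shape[0]),
                    tie=tie,
                    copies=copies,
                    start_bp=int(markers.position_bp[lo]),
                    end_bp=int(markers.position_bp[hi - 1]),
                )
            )
    return windows


def copies_matrix(windows: list[HaplotypeWindow]) -> np.ndarray:
    """(n_animals, n_windows) float G matrix, NaN where an animal was dropped."""
    G = np.stack([w.copies for w in windows], axis=1).astype(float)
    G[G == MISSING] = np.nan
    return G


# ---------------------------------------------------------------------------
# birth-year scan
# ---------------------------------------------------------------------------


def birthyear_haplotype_scan(
    windows: list[HaplotypeWindow],
    pedigree: PedigreeTable,
    animals: list[str],
    n_perm: int = 1000,
    rng_seed: int = 0,
) -> tuple[LogisticScanResult, PermutationThresholds]:
    """Logistic scan of top-haplotype carriage (G >= 1) on birth year per window.

    Carriage rather than the 0/1/2 copy count keeps the response binary, the
    form the logistic model expects; windows where carriage is constant are
    flagged non-estimable.
    """
    G = copies_matrix(windows)
    carriage = np.where(np.isnan(G), np.nan, (G >= 1).astype(float))
    years = pedigree.birth_years(animals)
    scan = logistic_scan(carriage, years)
    thr = permutation_thresholds(carriage, years, n_perm=n_perm, rng_seed=rng_seed)
    return scan, thr


def haplotype_scan_frame(
    windows: list[HaplotypeWindow], scan: LogisticScanResult
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "window_id": [w.window_id for w in windows],
            "chromosome": [w.chromosome for w in windows],
            "start_bp": [w.start_bp for w in windows],
            "end_bp": [w.end_bp for w in windows],
            "top_frequency": [w.top_frequency for w in windows],
        }
    )
    df["alpha"] = scan.alpha
    df["beta"] = scan.beta
    df["p_value"] = scan.p_value
    df["neg_log10_p"] = scan.neg_log10_p
    df["estimable"] = scan.estimable
    return df


# ---------------------------------------------------------------------------
# trait GLM
# ---------------------------------------------------------------------------


def _ols_slope(G: np.ndarray, y: np.ndarray):
    """Vectorised per-column simple regression of y on G (NaN-aware).

    Returns (mu, beta, se_beta, df, estimable).
    """
    mask = ~np.isnan(G) & ~np.isnan(y)[:, None]
    n = mask.sum(axis=0).astype(float)
    Gv = np.where(mask, G, 0.0)
    yv = np.where(mask, y[:, None], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        gbar = Gv.sum(axis=0) / n
        ybar = yv.sum(axis=0) / n
        sxx = (Gv**2).sum(axis=0) - n * gbar**2
        sxy = (Gv * yv).sum(axis=0) - n * gbar * ybar
        syy = (yv**2).sum(axis=0) - n * ybar**2
        beta = sxy / sxx
        mu = ybar - beta * gbar
        dof = n - 2
        rss = np.maximum(syy - beta * sxy, 0.0)
        se = np.sqrt(rss / np.maximum(dof, 1) / sxx)
    estimable = (sxx > 0) & (dof >= 1) & np.isfinite(se) & (se > 0)
    return mu, beta, se, dof, estimable


def trait_association(
    windows: list[HaplotypeWindow],
    traits: TraitTable,
    animals: list[str],
    trait: str = "milk",
    n_perm: int = 1000,
    rng_seed: int = 0,
) -> tuple[TraitAssocResult, PermutationThresholds]:
    """Additive GLM y = mu + beta G + e per window, with a permutation threshold.

    G counts copies of the window's most frequent haplotype; all other
    haplotypes contribute 0 by construction.  p is the two-sided t-test of
    beta = 0.  The experiment-wise threshold permutes trait values across
    animals and records the per-permutation maximum -log10 p; the 99th
    percentile is the 1% threshold (95th for 5%).
    """
    G = copies_matrix(windows)
    y = traits.values_for(animals, trait)
    mu, beta, se, dof, est = _ols_slope(G, y)
    p, nlp = _t_pvalues(beta, se, dof, est)
    result = TraitAssocResult(
        trait=trait,
        window_ids=[w.window_id for w in windows],
        mu=mu,
        beta=beta,
        p_value=p,
        neg_log10_p=nlp,
        estimable=est,
    )
    rng = np.random.default_rng(rng_seed)
    ok = ~np.isnan(y)
    maxima = np.empty(n_perm)
    Gok = G[ok]
    yok = y[ok]
    for k in range(n_perm):
        yp = rng.permutation(yok)
        _, b, s, d, e = _ols_slope(Gok, yp)
        _, nl = _t_pvalues(b, s, d, e)
        maxima[k] = np.nanmax(np.where(e, nl, np.nan)) if e.any() else 0.0
    thr = PermutationThresholds(
        n_perm,
        float(np.quantile(maxima, 0.95)),
        float(np.quantile(maxima, 0.99)),
        maxima,
    )
    return result, thr


def _t_pvalues(beta, se, dof, estimable):
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.abs(beta / se)
    logp = np.log(2.0) + stats.t.logsf(t, np.maximum(dof, 1))
    p = np.where(estimable, np.minimum(np.exp(logp), 1.0), np.nan)
    nlp = np.where(estimable, -logp / np.log(10.0), np.nan)
    return p, nlp


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def write_windows(windows: list[HaplotypeWindow], path: str | Path) -> None:
    rows = []
    for w in windows:
        rows.append(
            {
                "window_id": w.window_id,
                "chromosome": w.chromosome,
                "start_bp": w.start_bp,
                "end_bp": w.end_bp,
                "snp_count": w.snp_count,
                "n_haplotypes": len(w.catalogue),
                "top_haplotype": w.top_haplotype,
                "top_frequency": w.top_frequency,
                "tie": w.tie,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
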