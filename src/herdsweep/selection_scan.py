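"""Per-locus logistic regression of autozygosity state on birth year.

The temporal-change scan models each SNP's 0/1 ROH coverage status as
logit P(status = 1) = alpha + beta * b, with b the animal's birth year.  A
positive beta means autozygosity at the locus increased over the study period.
Genome-wide (experiment-wise) significance thresholds come from permutations:
birth years are shuffled across animals, the whole genome is rescanned, and
the maximum -log10 p is recorded; the 95th/99th percentiles of those maxima
are the 5% and 1% thresholds.

All loci share the same design matrix (intercept + centred birth year), so the
IRLS/Newton iterations are vectorised across loci; the per-locus 2x2 Newton
systems are solved in closed form.  This is what makes 1,000 permutation
rescans affordable.  Wald p-values are used throughout (cheap inside the
permutation loop); a likelihood-ratio test is available for individual loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MarkerMap

#: |beta| * (year range) beyond which the fit is declared separated
_SEPARATION_LOGIT = 30.0
_MAX_ITER = 60
_TOL = 1e-10


@dataclass
class LogisticScanResult:
    alpha: np.ndarray  # intercept (at the *original* year scale)
    beta: np.ndarray  # per-year log-odds change
    p_value: np.ndarray
    neg_log10_p: np.ndarray
    estimable: np.ndarray  # bool
    markers: MarkerMap | None = None

    def to_frame(self) -> pd.DataFrame:
        base = (
            self.markers.to_frame()[["snp_id", "chromosome", "position_bp"]]
            if self.markers is not None
            else pd.DataFrame(index=range(len(self.beta)))
        )
        base = base.copy()
        base["alpha"] = self.alpha
        base["beta"] = self.beta
        base["p_value"] = self.p_value
        base["neg_log10_p"] = self.neg_log10_p
        base["estimable"] = self.estimable
        return base


@dataclass
class PermutationThresholds:
    n_perm: int
    threshold_5pct: float  # -log10 p scale
    threshold_1pct: float
    maxima: np.ndarray  # per-permutation genome-wide maxima, for audit

    def __post_init__(self) -> None:
        if self.threshold_1pct < self.threshold_5pct:
            raise ValueError("1% threshold cannot lie below the 5% threshold")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": ["5pct", "1pct"],
                "neg_log10_p": [self.threshold_5pct, self.threshold_1pct],
                "n_perm": [self.n_perm, self.n_perm],
            }
        )


@dataclass
class CandidateRegion:
    chromosome: int
    start_bp: int
    end_bp: int
    peak_statistic: float
    peak_position_bp: int
    n_snps: int
    direction: float  # sign carrier (e.g. beta at the peak); 0 if not applicable
    rule_id: str

    @property
    def size_bp(self) -> int:
        return self.end_bp - self.start_bp


# ---------------------------------------------------------------------------
# vectorised IRLS with a shared two-column design
# ---------------------------------------------------------------------------


def _newton_loop(yt, wt, x, b0, b1, active_idx, estimable, x_range, tol, max_iter):
    """Newton iterations on the active rows of a locus-major response.

    ``yt``: (L, n) responses, ``wt``: (L, n) observation weights or None when
    no cells are excluded.  Updates ``b0``/``b1``/``estimable`` in place and
    returns the still-unconverged row indices.
    """
    dtype = yt.dtype
    xr = x[None, :]
    xx = (x * x)[None, :]
    for _ in range(max_iter):
        if active_idx.size == 0:
            break
        # active rows are contiguous gathers in the locus-major layout, so
        # shrinking the set really shrinks the work
        ya = yt[active_idx]
        eta = b0[active_idx][:, None] + b1[active_idx][:, None] * xr
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        if wt is None:
            w = p * (1.0 - p)
            r = ya - p
        else:
            wa = wt[active_idx]
            w = p * (1.0 - p) * wa
            r = (ya - p) * wa
        g0 = r.sum(axis=1)
        g1 = r @ x
        h00 = w.sum(axis=1)
        h01 = w @ x
        h11 = (w * xx).sum(axis=1)
        det = h00 * h11 - h01 * h01
        bad = det <= np.finfo(dtype).tiny
        det = np.where(bad, 1.0, det)
        d0 = np.where(bad, 0.0, (h11 * g0 - h01 * g1) / det)
        d1 = np.where(bad, 0.0, (h00 * g1 - h01 * g0) / det)
        b0[active_idx] += d0
        b1[active_idx] += d1
        sep = np.abs(b1[active_idx]) * x_range > _SEPARATION_LOGIT
        drop = sep | bad
        if drop.any():
            estimable[active_idx[drop]] = False
        keep = ~drop & ((np.abs(d0) > tol) | (np.abs(d1) > tol))
        active_idx = active_idx[keep]
    return active_idx


class _PreparedResponses:
    """Locus-major float64/float32 copies of a response matrix, built once."""

    def __init__(self, y: np.ndarray):
        n, L = y.shape
        mask = ~np.isnan(y)
        complete = bool(mask.all())
        self.yt64 = np.ascontiguousarray(np.where(mask, y, 0.0).T)
        self.wt64 = None if complete else np.ascontiguousarray(mask.T.astype(float))
        self.yt32 = self.yt64.astype(np.float32)
        self.wt32 = None if self.wt64 is None else self.wt64.astype(np.float32)
        self.n_eff = mask.sum(axis=0)
        self.n = n
        self.L = L


def _logistic_fit_shared(
    y: np.ndarray, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit logit P(y=1) = b0 + b1 * x for every column of ``y`` at once.

    ``y``: (n, L) float 0/1 with NaN for excluded cells; ``x``: (n,) covariate
    (pre-centred by the caller).  Returns (b0, b1, se1, estimable).

    The bulk of the iterations run in float32 on a locus-major copy (memory
    bandwidth dominates at genome scale); a float64 polish pass then drives
    every estimable locus to full Newton convergence.
    """
    return _logistic_fit_prepared(_PreparedResponses(y), x)


def _logistic_fit_prepared(
    prep: "_PreparedResponses", x: np.ndarray, precision: str = "full"
):
    """``precision="fast"`` stays in float32 throughout and skips the float64
    polish -- used inside permutation loops, where thresholds are empirical
    percentiles and the ~1e-4 difference in -log10 p is immaterial."""
    n, L = prep.n, prep.L
    yt64, wt64 = prep.yt64, prep.wt64
    n_eff = prep.n_eff
    n_ones = yt64.sum(axis=1)
    n_zeros = n_eff - n_ones
    estimable = (n_ones >= 2) & (n_zeros >= 2)

    x = x.astype(float)
    # start the intercept at the empirical log-odds
    with np.errstate(divide="ignore", invalid="ignore"):
        pbar = np.where(n_eff > 0, n_ones / np.maximum(n_eff, 1), 0.5)
    pbar = np.clip(pbar, 1e-6, 1 - 1e-6)
    b0 = np.log(pbar / (1 - pbar))
    b1 = np.zeros(L)
    x_range = float(np.ptp(x)) if n else 1.0

    # float32 phase (all-float32 operands, then copy the solution back)
    b0_32 = b0.astype(np.float32)
    b1_32 = b1.astype(np.float32)
    _newton_loop(
        prep.yt32,
        prep.wt32,
        x.astype(np.float32),
        b0_32,
        b1_32,
        np.flatnonzero(estimable),
        estimable,
        x_range,
        tol=1e-5,
        max_iter=_MAX_ITER,
    )
    b0 = b0_32.astype(float)
    b1 = b1_32.astype(float)
    if precision == "full":
        # float64 polish: Newton is quadratic, so one or two passes suffice
        _newton_loop(
            yt64,
            wt64,
            x,
            b0,
            b1,
            np.flatnonzero(estimable),
            estimable,
            x_range,
            tol=_TOL,
            max_iter=8,
        )

    # standard error of b1 from the inverse observed information
    if precision == "full":
        yt_se, wt_se, x_se = yt64, wt64, x
        b0_se, b1_se = b0, b1
    else:
        yt_se, wt_se, x_se = prep.yt32, prep.wt32, x.astype(np.float32)
        b0_se, b1_se = b0_32, b1_32
    eta = b0_se[:, None] + b1_se[:, None] * x_se[None, :]
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = p * (1.0 - p) if wt_se is None else p * (1.0 - p) * wt_se
    h00 = (w.sum(axis=1)).astype(float)
    h01 = (w @ x_se).astype(float)
    h11 = (w @ (x_se * x_se)).astype(float)
    det = h00 * h11 - h01 * h01
    with np.errstate(invalid="ignore", divide="ignore"):
        se1 = np.sqrt(np.where(det > 0, h00 / np.maximum(det, 1e-300), np.nan))
    estimable &= np.isfinite(se1) & (se1 > 0)
    return b0, b1, se1, estimable


def _wald(beta: np.ndarray, se: np.ndarray, estimable: np.ndarray):
    """Two-sided Wald p and -log10 p (via log-sf, stable for huge z)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.abs(beta / se)
    logp = np.log(2.0) + stats.norm.logsf(z)
    p = np.where(estimable, np.minimum(np.exp(logp), 1.0), np.nan)
    nlp = np.where(estimable, -logp / np.log(10.0), np.nan)
    return p, nlp


def logistic_scan(
    responses: np.ndarray,
    birth_years: np.ndarray,
    markers: MarkerMap | None = None,
) -> LogisticScanResult:
    """One logistic fit per response column against birth year.

    ``responses``: (n_animals, L) 0/1 (NaN allowed for animal x locus
    exclusions); ``birth_years``: per animal (NaN rows are dropped with a log
    message).  Birth year is centred at its mean internally for numerical
    stability; reported alpha is transformed back to the original year scale.
    """
    birth_years = np.asarray(birth_years, dtype=float)
    responses = np.asarray(responses, dtype=float)
    ok = ~np.isnan(birth_years)
    if not ok.all():
        import logging

        logging.getLogger("herdsweep").info(
            "dropping %d animals with missing birth year", int((~ok).sum())
        )
        responses = responses[ok]
        birth_years = birth_years[ok]
    centre = birth_years.mean()
    b0c, b1, se1, estimable = _logistic_fit_shared(responses, birth_years - centre)
    p, nlp = _wald(b1, se1, estimable)
    alpha = b0c - b1 * centre  # back to uncentred years
    nan = np.where(estimable, 0.0, np.nan)
    return LogisticScanResult(
        alpha=alpha + nan,
        beta=b1 + nan,
        p_value=p,
        neg_log10_p=nlp,
        estimable=estimable,
        markers=markers,
    )


def fit_locus_logistic(
    status: np.ndarray, birth_year: np.ndarray
) -> tuple[float, float, float]:
    """Single-locus convenience wrapper: returns (alpha, beta, wald_p).

    Non-estimable fits (constant status, complete separation, fewer than two
    animals in either class) return NaNs rather than raising.
    """
    res = logistic_scan(np.asarray(status, dtype=float)[:, None], birth_year)
    return float(res.alpha[0]), float(res.beta[0]), float(res.p_value[0])


def lrt_locus_logistic(status: np.ndarray, birth_year: np.ndarray) -> float:
    """Likelihood-ratio p-value for beta = 0 at one locus (for peak follow-up)."""
    status = np.asarray(status, dtype=float)
    ok = ~np.isnan(status) & ~np.isnan(birth_year)
    y = status[ok]
    x = birth_year[ok] - birth_year[ok].mean()
    a, b, _, est = _logistic_fit_shared(y[:, None], x)
    if not est[0]:
        return float("nan")
    eta = a[0] + b[0] * x
    ll1 = np.sum(y * eta - np.log1p(np.exp(np.clip(eta, -35, 35))))
    pbar = np.clip(y.mean(), 1e-12, 1 - 1e-12)
    ll0 = np.sum(y * np.log(pbar) + (1 - y) * np.log(1 - pbar))
    return float(stats.chi2.sf(2.0 * (ll1 - ll0), df=1))


def scan_genome(
    coverage: np.ndarray, birth_years: np.ndarray, markers: MarkerMap
) -> LogisticScanResult:
    """Genome scan of the ROH coverage indicator against birth year, map-aligned."""
    if coverage.shape[1] != markers.n_snps:
        raise ValueError("coverage matrix not aligned to the marker map")
    return logistic_scan(coverage, birth_years, markers)


def permutation_thresholds(
    responses: np.ndarray,
    birth_years: np.ndarray,
    n_perm: int = 1000,
    rng_seed: int = 0,
) -> PermutationThresholds:
    """Experiment-wise thresholds from permuted birth years.

    Each permutation shuffles birth years across animals (responses fixed,
    preserving the spatial correlation of ROH), rescans every locus, and keeps
    the genome-wide maximum -log10 p over estimable loci.  Thresholds are the
    empirical 95th / 99th percentiles of the maxima.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(rng_seed)
    birth_years = np.asarray(birth_years, dtype=float)
    responses = np.asarray(responses, dtype=float)
    ok = ~np.isnan(birth_years)
    responses = responses[ok]
    birth_years = birth_years[ok]
    x = birth_years - birth_years.mean()
    prep = _PreparedResponses(responses)
    maxima = np.empty(n_perm)
    for k in range(n_perm):
        xp = rng.permutation(x)
        _, b1, se1, est = _logistic_fit_prepared(prep, xp, precision="fast")
        _, nlp = _wald(b1, se1, est)
        maxima[k] = np.nanmax(np.where(est, nlp, np.nan)) if est.any() else 0.0
    t5 = float(np.quantile(maxima, 0.95))
    t1 = float(np.quantile(maxima, 0.99))
    return PermutationThresholds(n_perm, t5, t1, maxima)


# ---------------------------------------------------------------------------
# region calling
# ---------------------------------------------------------------------------


def call_regions(
    scan: LogisticScanResult,
    threshold: float,
    min_size_bp: int = 500_000,
    merge_gap_bp: int = 250_000,
    rule_id: str = "birthyear_scan",
) -> list[CandidateRegion]:
    """Merge above-threshold SNPs into candidate regions.

    Significant SNPs on the same chromosome are merged when separated by at
    most ``merge_gap_bp``; regions spanning <= ``min_size_bp`` are discarded.
    The peak SNP's statistic and its beta sign are attached.
    """
    if scan.markers is None:
        raise ValueError("region calling requires a map-aligned scan")
    markers = scan.markers
    sig = np.flatnonzero(scan.estimable & (scan.neg_log10_p > threshold))
    regions: list[CandidateRegion] = []
    if sig.size == 0:
        return regions
    groups: list[list[int]] = [[int(sig[0])]]
    for j in sig[1:]:
        prev = groups[-1][-1]
        same_chrom = markers.chromosome[j] == markers.chromosome[prev]
        close = markers.position_bp[j] - markers.position_bp[prev] <= merge_gap_bp
        if same_chrom and close:
            groups[-1].append(int(j))
        else:
            groups.append([int(j)])
    for grp in groups:
        idx = np.array(grp)
        start = int(markers.position_bp[idx[0]])
        end = int(markers.position_bp[idx[-1]])
        if end - start <= min_size_bp:
            continue
        peak = idx[np.argmax(scan.neg_log10_p[idx])]
        regions.append(
            CandidateRegion(
                chromosome=int(markers.chromosome[idx[0]]),
                start_bp=start,
                end_bp=end,
                peak_statistic=float(scan.neg_log10_p[peak]),
                peak_position_bp=int(markers.position_bp[peak]),
                n_snps=len(grp),
                direction=float(np.sign(scan.beta[peak])),
                rule_id=rule_id,
            )
        )
    return regions


def regions_frame(regions: list[CandidateRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chromosome": r.chromosome,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "size_bp": r.size_bp,
                "peak_statistic": r.peak_statistic,
                "peak_position_bp": r.peak_position_bp,
                "n_snps": r.n_snps,
                "direction": r.direction,
                "rule_id": r.rule_id,
            }
            for r in regions
        ],
        columns=[
            "chromosome",
            "start_bp",
            "end_bp",
            "size_bp",
            "peak_statistic",
            "peak_position_bp",
            "n_snps",
            "direction",
            "rule_id",
        ],
    )


def write_scan(scan: LogisticScanResult, path: str | Path) -> None:
    scan.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_thresholds(thr: PermutationThresholds, path: str | Path) -> None:
    thr.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_regions(regions: list[CandidateRegion], path: str | Path) -> None:
    regions_frame(regions).to_csv(path, sep="\t", index=False, float_format="%.6g")
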