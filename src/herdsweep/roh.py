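"""Runs of homozygosity, locus autozygosity F_L, and inbreeding coefficients.

An ROH is a maximal stretch of consecutive homozygous genotype calls in one
animal, reported only when it contains at least ``min_snps`` SNPs (default 50)
AND spans more than ``min_length_bp`` (default 1 Mb) — the two clauses are
enforced jointly.  Heterozygote tolerance is zero.  Missing calls break a run
by default; an optional bridge policy skips up to ``bridge_k`` consecutive
missing calls without counting them toward the SNP tally.

Locus autozygosity F_L at a SNP is the fraction of animals whose ROH cover
that SNP: F_L = (sum of per-animal 0/1 autozygous status) / N, with N the
number of genotyped animals in the input.

Per-animal genomic inbreeding f_roh is the summed ROH length divided by the
mapped (SNP-spanned) autosome length — the panel defines what is observable.
Pedigree inbreeding is Wright's F computed by the tabular additive-relationship
method: F_x = a(sire, dam) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, MarkerMap, PedigreeTable


@dataclass
class ROHSegment:
    animal_id: str
    chromosome: int
    start_snp_index: int  # flat panel index, inclusive
    end_snp_index: int  # inclusive
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class AutozygosityTrack:
    markers: MarkerMap
    fl: np.ndarray  # per-SNP F_L in [0, 1]
    n_animals: int
    fl_by_year_bin: pd.DataFrame | None = None  # optional trend display

    def to_frame(self) -> pd.DataFrame:
        df = self.markers.to_frame()[["snp_id", "chromosome", "position_bp"]].copy()
        df["fl"] = self.fl
        return df


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) inclusive index pairs of maximal True runs."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def _bridge_runs(
    state: np.ndarray, bridge_k: int
) -> list[tuple[int, int]]:
    """Maximal homozygous runs allowing gaps of <= bridge_k consecutive missing calls.

    ``state``: 1 homozygous, 0 heterozygous, -1 missing.  Returned segments
    start and end on homozygous SNPs.
    """
    hom_runs = _runs_of(state == 1)
    if not hom_runs:
        return []
    merged = [list(hom_runs[0])]
    for start, end in hom_runs[1:]:
        gap = state[merged[-1][1] + 1 : start]
        if len(gap) <= bridge_k and np.all(gap == MISSING):
            merged[-1][1] = end
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def detect_roh(
    g: GenotypeMatrix,
    min_snps: int = 50,
    min_length_bp: int = 1_000_000,
    missing_policy: str = "break",
    bridge_k: int = 0,
) -> list[ROHSegment]:
    """Detect ROH for every animal on every chromosome.

    A segment is reported iff it contains >= ``min_snps`` homozygous SNPs and
    spans strictly more than ``min_length_bp`` (end_bp - start_bp over the
    first and last SNP of the run).  ``missing_policy`` is ``"break"`` (a
    missing call terminates the run) or ``"skip"`` (up to ``bridge_k``
    consecutive missing calls are bridged without counting toward n_snps).
    """
    if missing_policy not in ("break", "skip"):
        raise ValueError("missing_policy must be 'break' or 'skip'")
    markers = g.markers
    segments: list[ROHSegment] = []
    chrom_slices = [(int(c), markers.chrom_slice(int(c))) for c in markers.chromosomes()]
    for i, animal in enumerate(g.animals):
        codes = g.codes[i]
        for chrom, sl in chrom_slices:
            sub = codes[sl]
            pos = markers.position_bp[sl]
            if missing_policy == "break":
                hom = (sub == 0) | (sub == 2)
                runs = _runs_of(hom)
                counts = [(s, e, e - s + 1) for s, e in runs]
            else:
                state = np.where(
                    sub == MISSING, MISSING, ((sub == 0) | (sub == 2)).astype(np.int8)
                )
                runs = _bridge_runs(state, bridge_k)
                counts = [
                    (s, e, int(np.sum((sub[s : e + 1] == 0) | (sub[s : e + 1] == 2))))
                    for s, e in runs
                ]
            for s, e, n_hom in counts:
                length = int(pos[e] - pos[s])
                if n_hom >= min_snps and length > min_length_bp:
                    segments.append(
                        ROHSegment(
                            animal_id=animal,
                            chromosome=chrom,
                            start_snp_index=sl.start + s,
                            end_snp_index=sl.start + e,
                            start_bp=int(pos[s]),
                            end_bp=int(pos[e]),
                            n_snps=n_hom,
                        )
                    )
    return segments


# ---------------------------------------------------------------------------
# F_L and f_roh
# ---------------------------------------------------------------------------


def coverage_matrix(rohs: list[ROHSegment], g: GenotypeMatrix) -> np.ndarray:
    """(n_animals, n_snps) 0/1 indicator: SNP j inside an ROH of animal i."""
    cover = np.zeros((g.n_animals, g.n_snps), dtype=np.int8)
    row = {a: i for i, a in enumerate(g.animals)}
    for seg in rohs:
        cover[row[seg.animal_id], seg.start_snp_index : seg.end_snp_index + 1] = 1
    return cover


def locus_autozygosity(
    rohs: list[ROHSegment],
    g: GenotypeMatrix,
    pedigree: PedigreeTable | None = None,
    year_bins: int = 5,
) -> AutozygosityTrack:
    """Per-SNP F_L = count of covering ROH / number of animals.

    With a pedigree, a per-birth-year-bin F_L table is attached for trend
    displays (equal-width year bins).
    """
    cover = coverage_matrix(rohs, g)
    fl = cover.mean(axis=0)
    by_year = None
    if pedigree is not None:
        years = pedigree.birth_years(g.animals)
        ok = ~np.isnan(years)
        if ok.any():
            edges = np.linspace(years[ok].min(), years[ok].max() + 1, year_bins + 1)
            rows = []
            for b in range(year_bins):
                sel = ok & (years >= edges[b]) & (years < edges[b + 1])
                if sel.any():
                    rows.append(
                        {
                            "year_lo": int(edges[b]),
                            "year_hi": int(edges[b + 1]),
                            "n_animals": int(sel.sum()),
                            "mean_fl": float(cover[sel].mean()),
                        }
                    )
            by_year = pd.DataFrame(rows)
    return AutozygosityTrack(g.markers, fl, g.n_animals, by_year)


def mapped_lengths(markers: MarkerMap) -> dict[int, int]:
    """Per-chromosome mapped length: last minus first SNP position."""
    out = {}
    for c in markers.chromosomes():
        pos = markers.position_bp[markers.chromosome == c]
        out[int(c)] = int(pos[-1] - pos[0])
    return out


def froh_per_animal(
    rohs: list[ROHSegment], markers: MarkerMap, animals: list[str]
) -> pd.DataFrame:
    """f_roh = total ROH length / total mapped autosome length, per animal."""
    total = sum(mapped_lengths(markers).values())
    length = {a: 0 for a in animals}
    for seg in rohs:
        length[seg.animal_id] += seg.length_bp
    return pd.DataFrame(
        {"animal_id": animals, "f_roh": [length[a] / total for a in animals]}
    )


# ---------------------------------------------------------------------------
# pedigree inbreeding
# ---------------------------------------------------------------------------


def _topological_order(ped: PedigreeTable) -> list:
    ids = list(ped.df["animal_id"])
    parents = {
        r.animal_id: [p for p in (r.sire_id, r.dam_id) if p is not None]
        for r in ped.df.itertuples(index=False)
    }
    order: list = []
    seen: set = set()

    def visit(node) -> None:
        stack = [(node, False)]
        while stack:
            n, done = stack.pop()
            if done:
                order.append(n)
                continue
            if n in seen:
                continue
            seen.add(n)
            stack.append((n, True))
            for p in parents.get(n, ()):
                if p in parents and p not in seen:
                    stack.append((p, False))

    for a in ids:
        visit(a)
    return order


def pedigree_inbreeding(ped: PedigreeTable) -> pd.DataFrame:
    """Wright's inbreeding coefficient by the tabular additive-relationship method.

    The numerator relationship matrix A is filled in topological (ancestors
    first) order: a(i,i) = 1 + a(s_i, d_i)/2 and a(i,j) = (a(s_i,j) + a(d_i,j))/2,
    unknown parents contributing 0.  F_i = a(s_i, d_i)/2; founders get F = 0.
    """
    order = _topological_order(ped)
    index = {a: k for k, a in enumerate(order)}
    n = len(order)
    parents = {
        r.animal_id: (r.sire_id, r.dam_id) for r in ped.df.itertuples(index=False)
    }
    A = np.zeros((n, n))
    for k, animal in enumerate(order):
        s, d = parents.get(animal, (None, None))
        si = index.get(s) if s is not None else None
        di = index.get(d) if d is not None else None
        rel = np.zeros(k)
        if si is not None:
            rel += 0.5 * A[si, :k]
        if di is not None:
            rel += 0.5 * A[di, :k]
        A[k, :k] = rel
        A[:k, k] = rel
        A[k, k] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
    f = {a: float(A[index[a], index[a]] - 1.0) for a in order}
    return pd.DataFrame(
        {
            "animal_id": ped.df["animal_id"],
            "f_ped": [f[a] for a in ped.df["animal_id"]],
        }
    )


def inbreeding_table(
    rohs: list[ROHSegment], g: GenotypeMatrix, ped: PedigreeTable
) -> pd.DataFrame:
    """Join f_roh (genomic) and f_ped (pedigree) per genotyped animal."""
    froh = froh_per_animal(rohs, g.markers, g.animals)
    fped = pedigree_inbreeding(ped)
    return froh.merge(fped, on="animal_id", how="left")


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def write_roh(rohs: list[ROHSegment], path: str | Path) -> None:
    """BED-like TSV (0-based half-open intervals, noted in the header)."""
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based half-open (BED convention)\n")
        fh.write("animal_id\tchromosome\tstart0\tend\tn_snps\n")
        for seg in rohs:
            fh.write(
                f"{seg.animal_id}\t{seg.chromosome}\t{seg.start_bp - 1}\t"
                f"{seg.end_bp}\t{seg.n_snps}\n"
            )
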