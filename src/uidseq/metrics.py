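"""Per-position base counts, error rates, detection limits and tracking.

The base-count table is a plain pandas DataFrame (one row per panel
position) with columns ``chrom, pos, ref, A, C, G, T, N, unique_depth,
raw_depth``.  ``unique_depth`` is the sum of A/C/G/T consensus calls (N
never counts as reference or alternate).  From it derive

* the per-position error rate: non-reference base fraction, after masking
  known germline SNP positions, low-depth positions (unique < 20 or raw
  < 200 by default) and systematic-error positions (> 10% non-reference);
* the detection limit at a position, defined as 1 / unique coverage — at
  249x unique coverage the smallest observable allele fraction is 0.4%;
* longitudinal tracking of known mutations (VAF, detected flag, limit);
* a cohort recurrence filter discarding variants seen in more than
  ``max_samples`` samples (systematic artifacts);
* concordance against an orthogonal single-molecule assay such as ddPCR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

_BASE_COLS = ["A", "C", "G", "T", "N"]
_CODE = np.full(256, 4, dtype=np.int64)  # anything unexpected counts as N
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def base_counts(
    reads: Sequence,
    panel_regions: Sequence[tuple[int, int]],
    reference: str,
    raw_reads: Sequence | None = None,
) -> pd.DataFrame:
    """Tally A/C/G/T/N per panel position over reads.

    ``reads`` are consensus reads (or any objects with ``chrom``,
    ``leftmost`` and ``sequence``); ``raw_reads`` optionally provides the
    pre-collapse reads whose interval coverage fills ``raw_depth``.  Reads
    that overlap no panel region are skipped and counted in the
    ``.attrs["off_target"]`` tally of the returned frame.
    """
    if not panel_regions:
        raise ValueError("at least one panel region is required")
    ref_len = len(reference)
    in_panel = np.zeros(ref_len, dtype=bool)
    for start, end in panel_regions:
        in_panel[start:end] = True

    counts = np.zeros((ref_len, 5), dtype=np.int64)
    chroms = {r.chrom for r in reads}
    if len(chroms) > 1:
        raise ValueError(f"reads span multiple chromosomes: {sorted(chroms)}")
    chrom = chroms.pop() if chroms else "chr1"
    off_target = 0
    for read in reads:
        left = read.leftmost
        seq = np.frombuffer(read.sequence.encode("ascii"), dtype=np.uint8)
        lo = max(left, 0)
        hi = min(left + len(seq), ref_len)
        if hi <= lo or not in_panel[lo:hi].any():
            off_target += 1
            continue
        codes = _CODE[seq[lo - left : hi - left]]
        np.add.at(counts, (np.arange(lo, hi), codes), 1)

    raw_depth = np.zeros(ref_len, dtype=np.int64)
    if raw_reads is not None:
        diff = np.zeros(ref_len + 1, dtype=np.int64)
        for read in raw_reads:
            lo = max(read.leftmost, 0)
            hi = min(read.leftmost + len(read.sequence), ref_len)
            if hi > lo:
                diff[lo] += 1
                diff[hi] -= 1
        raw_depth = diff[:-1].cumsum()

    pos = np.flatnonzero(in_panel)
    ref_arr = np.frombuffer(reference.encode("ascii"), dtype=np.uint8)
    table = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref": [chr(b) for b in ref_arr[pos]],
            **{col: counts[pos, i] for i, col in enumerate(_BASE_COLS)},
        }
    )
    table["unique_depth"] = table[["A", "C", "G", "T"]].sum(axis=1)
    table["raw_depth"] = raw_depth[pos]
    table.attrs["off_target"] = off_target
    return table


@dataclass(frozen=True)
class ErrorRateResult:
    """Per-position error rates and their sample-level mean."""

    positions: pd.DataFrame     # retained positions with an ``error_rate`` column
    sample_rate: float          # unweighted mean over retained positions
    n_retained: int
    exclusions: dict[str, int]  # positions failing each filter (filters overlap)


def error_rate(
    table: pd.DataFrame,
    known_snp_positions: Iterable[int] = (),
    min_unique_depth: int = 20,
    min_raw_depth: int = 200,
    max_position_error: float = 0.10,
) -> ErrorRateResult:
    """Background error rate under SNP, depth and systematic-error filters.

    A position's error rate is the fraction of non-reference bases among
    its A/C/G/T calls.  Positions are discarded when they are known
    germline SNPs, when unique depth < ``min_unique_depth`` or raw depth
    < ``min_raw_depth`` (inflated rates at low coverage), or when the rate
    exceeds ``max_position_error`` (systematic artifacts).  The filters
    are position-local, so their order cannot change the retained set.
    """
    t = table.copy()
    ref_count = np.zeros(len(t), dtype=np.int64)
    for b in "ACGT":
        mask = (t["ref"] == b).to_numpy()
        ref_count[mask] = t.loc[mask, b].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = (t["unique_depth"].to_numpy() - ref_count) / t["unique_depth"].to_numpy()
    t["error_rate"] = rate

    snp = t["pos"].isin(set(known_snp_positions)).to_numpy()
    low_unique = t["unique_depth"].to_numpy() < min_unique_depth
    low_raw = t["raw_depth"].to_numpy() < min_raw_depth
    high = np.nan_to_num(rate, nan=1.0) > max_position_error
    keep = ~(snp | low_unique | low_raw | high)
    retained = t.loc[keep].reset_index(drop=True)
    if retained.empty:
        raise ValueError("no positions retained after filtering")
    return ErrorRateResult(
        positions=retained,
        sample_rate=float(retained["error_rate"].mean()),
        n_retained=len(retained),
        exclusions={
            "snp": int(snp.sum()),
            "low_unique_depth": int(low_unique.sum()),
            "low_raw_depth": int(low_raw.sum()),
            "high_error": int(high.sum()),
        },
    )


def detection_limit(unique_coverage: float) -> float:
    """Smallest observable allele fraction at a position: 1 / coverage."""
    if unique_coverage <= 0:
        raise ValueError("detection limit undefined at zero coverage")
    return 1.0 / unique_coverage


def format_detection_limit(unique_coverage: float) -> str:
    """Detection limit as a printed percentage, e.g. 249x -> '0.4%'.

    Uses two significant digits with trailing zeros stripped (0.402% ->
    0.4%, 0.18% stays 0.18%); values of 10% or more print as integers.
    """
    pct = 100.0 * detection_limit(unique_coverage)
    if pct >= 10:
        return f"{pct:.0f}%"
    text = f"{pct:.2g}".rstrip("0").rstrip(".")
    return f"{text}%"


def required_coverage(allele_fraction: float) -> int:
    """Unique coverage needed to observe one mutated fragment: ceil(1/AF)."""
    if not 0 < allele_fraction <= 1:
        raise ValueError("allele_fraction must be in (0, 1]")
    return math.ceil(1.0 / allele_fraction - 1e-9)


def track_mutations(
    table: pd.DataFrame,
    mutations: Sequence[tuple],
    detection_threshold: int = 1,
) -> pd.DataFrame:
    """VAF, detection flag and per-position detection limit for known sites.

    ``mutations`` are (chrom, pos, ref, alt) tuples.  Detection means at
    least ``detection_threshold`` alternate-allele consensus reads (the
    single-molecule convention, mirroring one positive droplet in ddPCR).
    Sites outside the covered panel are reported with missing depth.
    """
    idx = table.set_index(["chrom", "pos"])
    rows = []
    for chrom, pos, ref, alt in mutations:
        key = (chrom, pos)
        if key in idx.index:
            row = idx.loc[key]
            depth = int(row["unique_depth"])
            alt_count = int(row[alt]) if alt in _BASE_COLS[:4] else 0
            vaf = alt_count / depth if depth > 0 else 0.0
            limit = 1.0 / depth if depth > 0 else np.nan
        else:
            depth, alt_count, vaf, limit = np.nan, 0, np.nan, np.nan
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "alt_count": alt_count,
                "unique_depth": depth,
                "vaf": vaf,
                "detected": bool(alt_count >= detection_threshold),
                "detection_limit": limit,
            }
        )
    return pd.DataFrame(rows)


def recurrence_filter(
    calls_by_sample: Mapping[str, pd.DataFrame], max_samples: int = 3
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Drop variants detected in more than ``max_samples`` samples.

    Variants recurring across many unrelated samples are far more likely
    systematic errors than genuine somatic events.  Input frames need
    ``chrom, pos, ref, alt`` columns; rows with a ``detected`` column set
    to False do not count towards recurrence.  Returns the filtered
    per-sample frames and a removal log.
    """
    if not calls_by_sample:
        raise ValueError("at least one sample is required")
    key_cols = ["chrom", "pos", "ref", "alt"]
    counts: dict[tuple, int] = {}
    for df in calls_by_sample.values():
        det = df if "detected" not in df.columns else df.loc[df["detected"]]
        for key in det[key_cols].itertuples(index=False, name=None):
            counts[key] = counts.get(key, 0) + 1
    recurrent = {k for k, c in counts.items() if c > max_samples}
    filtered = {}
    for sample, df in calls_by_sample.items():
        keys = list(df[key_cols].itertuples(index=False, name=None))
        mask = np.array([k not in recurrent for k in keys])
        filtered[sample] = df.loc[mask].reset_index(drop=True)
    removed = pd.DataFrame(
        [dict(zip(key_cols, k), n_samples=counts[k]) for k in sorted(recurrent)],
        columns=key_cols + ["n_samples"],
    )
    return filtered, removed


@dataclass(frozen=True)
class ConcordanceResult:
    """Cross-platform agreement, with the orthogonal assay as gold standard."""

    n_truth_detected: int
    n_both_detected: int
    sensitivity_pct: float        # one decimal; NaN when undefined
    sensitivity_defined: bool
    af_pearson_r: float           # over positions detected by both; NaN if < 2
    per_mutation: pd.DataFrame    # merged table with coverage-sufficiency flags


def concordance(ngs: pd.DataFrame, truth: pd.DataFrame) -> ConcordanceResult:
    """Sensitivity and AF correlation of tracked mutations against a truth
    table from an orthogonal assay.

    ``ngs`` needs ``chrom, pos, detected, vaf, unique_depth`` (the output
    of :func:`track_mutations`); ``truth`` needs ``chrom, pos, detected,
    af``.  Sensitivity is the percentage of truth-detected mutations also
    detected in the sequencing data, to one decimal.  Each mutation is
    flagged for whether its unique coverage reaches
    :func:`required_coverage` of the truth allele fraction.
    """
    merged = truth.merge(
        ngs, on=["chrom", "pos"], how="inner", suffixes=("_truth", "_ngs")
    )
    truth_det = merged.loc[merged["detected_truth"]]
    n_truth = len(truth_det)
    n_both = int(truth_det["detected_ngs"].sum())
    if n_truth == 0:
        sens, defined = float("nan"), False
    else:
        sens, defined = round(100.0 * n_both / n_truth, 1), True

    both = merged.loc[merged["detected_truth"] & merged["detected_ngs"]]
    if len(both) >= 2 and both["af"].nunique() > 1 and both["vaf"].nunique() > 1:
        r = float(sps.pearsonr(both["af"], both["vaf"])[0])
    else:
        r = float("nan")

    suff = []
    for _, row in merged.iterrows():
        af = row["af"]
        cov = row["unique_depth"]
        if not (af and af > 0) or pd.isna(cov):
            suff.append(False)
        else:
            suff.append(bool(cov >= required_coverage(af)))
    per_mut = merged.assign(coverage_sufficient=suff)
    return ConcordanceResult(
        n_truth_detected=n_truth,
        n_both_detected=n_both,
        sensitivity_pct=sens,
        sensitivity_defined=defined,
        af_pearson_r=r,
        per_mutation=per_mut,
    )


def call_variants_naive(table: pd.DataFrame, min_alt: int = 2) -> pd.DataFrame:
    """Naive de novo scan: alternate alleles with >= ``min_alt`` consensus
    reads and VAF above the position detection limit.

    This is a simple base-count screen, not a somatic variant caller: it
    models no strand artifacts, mapping noise or germline contamination.
    """
    rows = []
    for _, row in table.iterrows():
        depth = row["unique_depth"]
        if depth <= 0:
            continue
        for base in "ACGT":
            if base == row["ref"]:
                continue
            count = int(row[base])
            vaf = count / depth
            if count >= min_alt and vaf > 1.0 / depth:
                rows.append(
                    {
                        "chrom": row["chrom"],
                        "pos": int(row["pos"]),
                        "ref": row["ref"],
                        "alt": base,
                        "alt_count": count,
                        "unique_depth": int(depth),
                        "vaf": vaf,
                    }
                )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "alt_count", "unique_depth", "vaf"]
    )
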