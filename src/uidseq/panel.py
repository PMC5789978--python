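"""Gene-panel design from a patient-by-gene somatic mutation catalog.

Genes are ranked by somatic mutation density (mutational events per coding
nucleotide, exons only) and the panel is the smallest prefix of that
ranking for which more than a target fraction of patients carries at least
``target_k`` detectable mutations inside the panel.  Extra regions of
known relevance (e.g. a frequently mutated promoter) can be forced into
the selection; they add to the panel footprint without entering the
ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class MutationCatalog:
    """Patient x gene somatic mutation counts plus per-gene coding length.

    ``counts`` is a DataFrame indexed by patient identifier with one column
    per gene (non-negative integers); ``gene_lengths`` is a Series mapping
    gene name to coding length in bp (> 0).
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series

    def __post_init__(self):
        if self.counts.shape[1] == 0 or self.counts.shape[0] == 0:
            raise ValueError("empty mutation catalog")
        missing = set(self.counts.columns) - set(self.gene_lengths.index)
        if missing:
            raise ValueError(f"genes without coding length: {sorted(missing)}")
        if (self.gene_lengths.loc[list(self.counts.columns)] <= 0).any():
            raise ValueError("coding lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("mutation counts must be non-negative")

    @property
    def patients(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class PanelSelection:
    """Result of panel selection over a ranked gene list."""

    ranking: pd.DataFrame            # gene, length, total, density, cumulative_bp
    target_k: int
    target_fraction: float
    curve: np.ndarray                # detectability at target_k for m = 1..G
    n_genes: int                     # selected ranking prefix length
    selected_genes: tuple[str, ...]
    forced_regions: tuple[tuple[str, int], ...]   # (name, length bp)
    shortfall: bool                  # target unreachable even with all genes


def rank_genes(catalog: MutationCatalog) -> pd.DataFrame:
    """Rank genes by mutations per coding nucleotide, descending.

    Ties are broken by larger total mutation count, then by gene name.
    Returns a DataFrame with columns ``gene``, ``length``, ``total``,
    ``density`` and ``cumulative_bp`` (running panel size along the
    ranking).
    """
    totals = catalog.counts.sum(axis=0)
    lengths = catalog.gene_lengths.loc[list(catalog.counts.columns)]
    df = pd.DataFrame(
        {
            "gene": list(catalog.counts.columns),
            "length": lengths.to_numpy(),
            "total": totals.to_numpy(),
        }
    )
    df["density"] = df["total"] / df["length"]
    df = df.sort_values(
        by=["density", "total", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)
    df["cumulative_bp"] = df["length"].cumsum()
    return df


def detectability_curve(
    catalog: MutationCatalog, ranking: pd.DataFrame | Sequence[str], k: int
) -> np.ndarray:
    """Fraction of patients with >= k mutations in the top-m genes, m = 1..G.

    ``k`` larger than any patient's total simply yields an all-zero curve.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    genes = (
        list(ranking["gene"]) if isinstance(ranking, pd.DataFrame) else list(ranking)
    )
    ordered = catalog.counts.loc[:, genes].to_numpy()
    cum = ordered.cumsum(axis=1)
    return (cum >= k).mean(axis=0)


def select_panel(
    catalog: MutationCatalog,
    target_k: int = 3,
    target_fraction: float = 0.5,
    forced_regions: Sequence[tuple[str, int]] = (),
) -> PanelSelection:
    """Choose the smallest ranking prefix exceeding the detectability target.

    Selects the smallest m such that the fraction of patients with at least
    ``target_k`` detectable mutations in the top-m genes is strictly
    greater than ``target_fraction``.  If the target is unreachable with
    every gene included, all genes are selected and ``shortfall`` is set.
    Forced regions are appended to the selection (and to the panel size)
    without affecting the ranking.
    """
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0, 1]")
    ranking = rank_genes(catalog)
    curve = detectability_curve(catalog, ranking, target_k)
    above = np.flatnonzero(curve > target_fraction)
    if above.size:
        n_genes = int(above[0]) + 1
        shortfall = False
    else:
        n_genes = len(ranking)
        shortfall = True
    return PanelSelection(
        ranking=ranking,
        target_k=target_k,
        target_fraction=target_fraction,
        curve=curve,
        n_genes=n_genes,
        selected_genes=tuple(ranking["gene"].iloc[:n_genes]),
        forced_regions=tuple((str(n), int(l)) for n, l in forced_regions),
        shortfall=shortfall,
    )


def panel_size(selection: PanelSelection) -> int:
    """Total panel footprint: selected coding bp plus forced-region bp."""
    gene_bp = int(selection.ranking["length"].iloc[: selection.n_genes].sum())
    forced_bp = sum(l for _, l in selection.forced_regions)
    return gene_bp + forced_bp


def synthetic_catalog(
    n_patients: int = 476,
    n_genes: int = 300,
    seed: int = 0,
    mean_mutations_per_patient: float = 6.0,
    hot_gene_shape: float = 0.35,
    patient_burden_sd: float = 0.5,
    length_log_mean: float = np.log(2000.0),
    length_log_sd: float = 0.6,
) -> MutationCatalog:
    """Generate a sparse patient x gene mutation catalog.

    Emulates the shape of a public tumor-cohort mutation table: gene coding
    lengths are lognormal (median ~2 kb); per-nucleotide mutation rates are
    gamma-distributed with a small shape parameter so that a handful of
    driver genes concentrate most events; patient mutational burden varies
    lognormally.  Counts are Poisson given gene rate x length x patient
    burden, scaled so the cohort mean is ``mean_mutations_per_patient``
    events per patient across all genes.
    """
    rng = np.random.default_rng(seed)
    lengths = np.round(rng.lognormal(length_log_mean, length_log_sd, n_genes)).astype(int)
    lengths = np.maximum(lengths, 150)
    rates = rng.gamma(hot_gene_shape, 1.0, n_genes)          # per-nt propensity
    burden = rng.lognormal(0.0, patient_burden_sd, n_patients)
    burden /= burden.mean()
    lam = np.outer(burden, rates * lengths)
    lam *= mean_mutations_per_patient / lam.sum(axis=1).mean()
    counts = rng.poisson(lam)
    genes = [f"G{i:03d}" for i in range(n_genes)]
    patients = [f"P{i:04d}" for i in range(n_patients)]
    return MutationCatalog(
        counts=pd.DataFrame(counts, index=patients, columns=genes),
        gene_lengths=pd.Series(lengths, index=genes),
    )
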