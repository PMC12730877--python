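"""Mutation-versus-selection inference on codon usage.

Two complementary gene-level analyses:

* **Neutrality plot** — ordinary least-squares regression of per-gene GC12 on
  GC3.  Under pure mutational pressure all codon positions drift together and
  the slope approaches 1; selection on codon usage decouples the (mostly
  non-synonymous) first and second positions from the (mostly synonymous)
  third, flattening the slope.  The selective constraint is summarised as
  ``selection% = (1 - |slope|) * 100``.

* **ENC/GC3 plot** — each gene's observed ENC is compared with the value
  expected under GC bias alone, ``ENCexp = 2 + s + 29/(s^2 + (1-s)^2)`` with
  ``s`` the gene's GC3 (Wright 1990).  Genes falling below the curve
  (``dNCsg = ENCobs - ENCexp < 0``) are called under selection for codon
  usage; ``dNC`` is the percentage of such genes in a genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cds_io import GeneRecord
from .codon_metrics import GenomeProfile, genome_profile, per_gene_metrics

#: constant in Wright's expected-ENC curve (the numerator of the 1/F term sum)
ENC_CURVE_CONSTANT = 29.0

#: two-sided p-value threshold for a "significant" GC12~GC3 correlation
NEUTRALITY_ALPHA = 0.01


@dataclass
class NeutralityFit:
    """OLS fit of GC12 on GC3 over the genes of one genome."""

    slope: float
    intercept: float
    r: float
    p_value: float
    n_genes: int
    stderr: float
    alpha: float = NEUTRALITY_ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    @property
    def abs_slope(self) -> float:
        return abs(self.slope)

    @property
    def selection_pct(self) -> float:
        """Selective constraint in percent.

        A non-significant correlation is itself a sign of selection dominating
        codon usage, so such fits report 100 (callers can inspect
        ``significant`` to flag them).
        """
        if not self.significant:
            return 100.0
        return selection_percent(self.abs_slope)


def neutrality_fit(
    gc3: Sequence[float],
    gc12: Sequence[float],
    alpha: float = NEUTRALITY_ALPHA,
) -> NeutralityFit:
    """Unweighted OLS of per-gene GC12 on GC3 (each gene one point)."""
    x = np.asarray(gc3, dtype=float)
    y = np.asarray(gc12, dtype=float)
    if x.shape != y.shape:
        raise ValueError("gc3 and gc12 must have equal length")
    if x.size < 3:
        raise ValueError(f"neutrality fit requires >= 3 genes, got {x.size}")
    if np.ptp(x) == 0.0:
        raise ValueError("GC3 is constant across genes; slope undefined")
    fit = stats.linregress(x, y)
    return NeutralityFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n_genes=int(x.size),
        stderr=float(fit.stderr),
        alpha=alpha,
    )


def selection_percent(abs_slope: float) -> float:
    """Selection on codon usage (%) = (1 - |neutrality slope|) * 100.

    Values above 1 give a negative percentage; callers should flag these.
    """
    if abs_slope < 0:
        raise ValueError("abs_slope must be non-negative")
    return (1.0 - abs_slope) * 100.0


def enc_expected(gc3: float | np.ndarray, constant: float = ENC_CURVE_CONSTANT):
    """Expected ENC under GC bias alone: 2 + s + constant/(s^2 + (1-s)^2)."""
    s = np.asarray(gc3, dtype=float)
    if np.any((s < 0.0) | (s > 1.0)):
        raise ValueError("gc3 must lie in [0, 1]")
    value = 2.0 + s + constant / (s**2 + (1.0 - s) ** 2)
    return float(value) if np.isscalar(gc3) or value.ndim == 0 else value


def gene_selection_calls(
    metrics: pd.DataFrame, constant: float = ENC_CURVE_CONSTANT
) -> pd.DataFrame:
    """Per-gene ENC/GC3 selection calls.

    ``metrics`` is a per-gene table with columns ``gene_id``, ``gc3`` and
    ``enc`` (as from :func:`cubtools.codon_metrics.per_gene_metrics`).  Genes
    with undefined ENC keep NaN ``dnc_sg`` and ``under_selection = False``;
    they are excluded from the dNC denominator by :func:`dnc_percent`.
    """
    calls = metrics.loc[:, [c for c in ("gene_id", "genome_id") if c in metrics]].copy()
    calls["enc_obs"] = metrics["enc"].to_numpy(dtype=float)
    calls["enc_exp"] = enc_expected(metrics["gc3"].to_numpy(dtype=float), constant)
    calls["dnc_sg"] = calls["enc_obs"] - calls["enc_exp"]
    calls["under_selection"] = calls["dnc_sg"] < 0  # strict; ties are not selection
    return calls


def dnc_percent(calls: pd.DataFrame) -> float:
    """dNC = 100 * (genes with dNCsg < 0) / (genes with defined ENC)."""
    defined = calls["dnc_sg"].notna()
    n = int(defined.sum())
    if n == 0:
        raise ValueError("no genes with defined ENC")
    return 100.0 * float(calls.loc[defined, "under_selection"].sum()) / n


def selected_subset_profile(
    genes: Sequence[GeneRecord],
    calls: pd.DataFrame,
    genome_id: str | None = None,
    group: str | None = None,
) -> GenomeProfile:
    """Pooled profile of only the genes called under selection (below the curve)."""
    selected_ids = set(calls.loc[calls["under_selection"], "gene_id"])
    subset = [g for g in genes if g.gene_id in selected_ids]
    if not subset:
        raise ValueError(
            "no genes fall below the expected ENC/GC3 curve; "
            "the selected-subset profile is undefined for this genome"
        )
    return genome_profile(subset, genome_id=genome_id, group=group)


def analyze_genome(
    genes: Sequence[GeneRecord],
    genome_id: str | None = None,
    group: str | None = None,
    curve_constant: float = ENC_CURVE_CONSTANT,
    alpha: float = NEUTRALITY_ALPHA,
) -> tuple[GenomeProfile, pd.DataFrame, pd.DataFrame]:
    """Full single-genome selection analysis.

    Returns ``(profile, per_gene_metrics, selection_calls)`` where ``profile``
    carries the neutrality fit and dNC percentage.
    """
    profile = genome_profile(genes, genome_id=genome_id, group=group)
    metrics = per_gene_metrics(genes)
    profile.neutrality = neutrality_fit(metrics["gc3"], metrics["gc12"], alpha=alpha)
    calls = gene_selection_calls(metrics, constant=curve_constant)
    profile.dnc_pct = dnc_percent(calls)
    return profile, metrics, calls


def neutrality_table(fits: dict[str, NeutralityFit]) -> pd.DataFrame:
    rows = []
    for genome_id, fit in fits.items():
        rows.append(
            {
                "genome_id": genome_id,
                "n_genes": fit.n_genes,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r": fit.r,
                "p_value": fit.p_value,
                "abs_slope": fit.abs_slope,
                "selection_pct": fit.selection_pct,
                "significant": fit.significant,
            }
        )
    return pd.DataFrame(rows)

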