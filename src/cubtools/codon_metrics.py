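"""Codon-usage indices: amino-acid composition, RSCU, positional GC, Wright's ENC.

All indices exclude the terminal stop codon.  Genome-wide values are computed
on codon counts pooled over all genes of a genome (the ``-totals`` convention),
not as means of per-gene values, so genes are implicitly weighted by length.

The effective number of codons (ENC) follows Wright (1990): for each
synonymous family the codon "homozygosity" is estimated with the
small-sample-corrected estimator

    F_hat = (n * sum(p_i^2) - 1) / (n - 1),      p_i = count_i / n,

and ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, where Fk is the mean of the defined
family homozygosities within the degeneracy-k class and the leading 2 accounts
for Met and Trp.  If the three-fold class (Ile) is missing it is imputed as
(F2 + F4)/2; ENC is capped at 61.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cds_io import GeneRecord
from .genetic_code import (
    CODON_TO_AA,
    DEGENERACY_CLASSES,
    FAMILIES,
    SENSE_CODONS,
    STOP_CODONS,
)

logger = logging.getLogger(__name__)

#: RSCU thresholds for calling a codon over-/under-represented
RSCU_OVER = 1.6
RSCU_UNDER = 0.6

#: genome/gene ENC at or below this value indicates strong codon bias
ENC_STRONG_BIAS = 35.0


@dataclass
class CodonCounts:
    """Counts of the 61 sense codons (and stops) for a gene or pooled genome."""

    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in SENSE_CODONS}
    )
    stop_counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in STOP_CODONS}
    )

    @property
    def n_codons(self) -> int:
        """Total sense-codon count (stops excluded)."""
        return sum(self.counts.values())

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        out = CodonCounts()
        for c in SENSE_CODONS:
            out.counts[c] = self.counts[c] + other.counts[c]
        for c in STOP_CODONS:
            out.stop_counts[c] = self.stop_counts[c] + other.stop_counts[c]
        return out

    def family_counts(self, aa: str) -> list[int]:
        return [self.counts[c] for c in FAMILIES[aa]]


def count_codons(sequence: str) -> CodonCounts:
    """Count non-overlapping in-frame codons; terminal stop goes to stop_counts.

    Internal stop codons (which should not occur after QC) are also recorded in
    ``stop_counts`` and logged.
    """
    if len(sequence) % 3 != 0:
        raise ValueError(f"sequence length {len(sequence)} not divisible by 3")
    out = CodonCounts()
    n = len(sequence) // 3
    internal_stops = 0
    for i in range(n):
        codon = sequence[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            out.stop_counts[codon] += 1
            if i < n - 1:
                internal_stops += 1
        elif codon in out.counts:
            out.counts[codon] += 1
        else:
            raise ValueError(f"non-ACGT codon {codon!r} at position {3 * i}")
    if internal_stops:
        logger.warning("sequence contains %d internal stop codon(s)", internal_stops)
    return out


def pooled_counts(genes: Iterable[GeneRecord | str]) -> CodonCounts:
    """Pool codon counts over genes (GeneRecords or raw sequences)."""
    total = CodonCounts()
    for gene in genes:
        seq = gene.sequence if isinstance(gene, GeneRecord) else gene
        total = total + count_codons(seq)
    return total


def aa_composition(counts: CodonCounts) -> dict[str, float]:
    """Amino-acid frequencies in percent (stop codons excluded)."""
    n = counts.n_codons
    if n == 0:
        raise ValueError("cannot compute amino-acid composition of zero codons")
    totals: Counter[str] = Counter()
    for codon, k in counts.counts.items():
        totals[CODON_TO_AA[codon]] += k
    return {aa: 100.0 * totals.get(aa, 0) / n for aa in FAMILIES}


@dataclass
class RscuVector:
    """RSCU per codon; NaN marks families with zero counts (undefined, not 0)."""

    values: dict[str, float]
    flags: dict[str, str]  # overrepresented / underrepresented / neutral / undefined


def rscu(
    counts: CodonCounts,
    over_threshold: float = RSCU_OVER,
    under_threshold: float = RSCU_UNDER,
) -> RscuVector:
    """Relative synonymous codon usage: observed / (family total / degeneracy).

    Single-codon families (Met, Trp) are reported as 1 when present.  Families
    with zero counts yield NaN so cross-genome averaging can skip missing data.
    """
    values: dict[str, float] = {}
    flags: dict[str, str] = {}
    for aa, codons in FAMILIES.items():
        family_total = sum(counts.counts[c] for c in codons)
        k = len(codons)
        for c in codons:
            if family_total == 0:
                values[c] = math.nan
                flags[c] = "undefined"
            elif k == 1:
                values[c] = 1.0
                flags[c] = "neutral"
            else:
                v = counts.counts[c] / (family_total / k)
                values[c] = v
                if v > over_threshold:
                    flags[c] = "overrepresented"
                elif v < under_threshold:
                    flags[c] = "underrepresented"
                else:
                    flags[c] = "neutral"
    return RscuVector(values=values, flags=flags)


@dataclass(frozen=True)
class PositionalGc:
    gc1: float
    gc2: float
    gc3: float

    @property
    def gc12(self) -> float:
        return (self.gc1 + self.gc2) / 2.0


def _strip_terminal_stop(sequence: str) -> str:
    if len(sequence) >= 3 and sequence[-3:] in STOP_CODONS:
        return sequence[:-3]
    return sequence


def positional_gc(sequence: str) -> PositionalGc:
    """GC fraction at codon positions 1-3 over sense codons (terminal stop excluded)."""
    if len(sequence) % 3 != 0:
        raise ValueError(f"sequence length {len(sequence)} not divisible by 3")
    sense = _strip_terminal_stop(sequence)
    n = len(sense) // 3
    if n == 0:
        raise ValueError("no sense codons")
    gc = [0, 0, 0]
    for i in range(n):
        for j in range(3):
            if sense[3 * i + j] in "GC":
                gc[j] += 1
    return PositionalGc(gc1=gc[0] / n, gc2=gc[1] / n, gc3=gc[2] / n)


def positional_gc_from_counts(counts: CodonCounts) -> PositionalGc:
    """Positional GC from pooled codon counts (codon-count weighted)."""
    n = counts.n_codons
    if n == 0:
        raise ValueError("no sense codons")
    gc = [0, 0, 0]
    for codon, k in counts.counts.items():
        for j in range(3):
            if codon[j] in "GC":
                gc[j] += k
    return PositionalGc(gc1=gc[0] / n, gc2=gc[1] / n, gc3=gc[2] / n)


def codon_homozygosity(family_counts: Sequence[int]) -> float:
    """Corrected homozygosity F_hat = (n * sum p_i^2 - 1) / (n - 1); NaN if n <= 1."""
    if any(k < 0 for k in family_counts):
        raise ValueError("negative codon counts")
    n = sum(family_counts)
    if n <= 1:
        return math.nan
    sum_p2 = sum((k / n) ** 2 for k in family_counts)
    return (n * sum_p2 - 1.0) / (n - 1.0)


def enc(counts: CodonCounts, cap: float = 61.0) -> float:
    """Wright's effective number of codons on (gene or pooled) codon counts.

    Returns NaN when a degeneracy class other than the three-fold one has no
    family with a defined, positive homozygosity.
    """
    class_means: dict[int, float] = {}
    for k, aas in DEGENERACY_CLASSES.items():
        if k == 1:
            continue
        f_values = []
        for aa in aas:
            f = codon_homozygosity(counts.family_counts(aa))
            if not math.isnan(f) and f > 0.0:
                f_values.append(f)
        if f_values:
            class_means[k] = float(np.mean(f_values))
    if 3 not in class_means and 2 in class_means and 4 in class_means:
        # Wright's recipe: impute the Ile class from its neighbours
        class_means[3] = (class_means[2] + class_means[4]) / 2.0
    if any(k not in class_means for k in (2, 3, 4, 6)):
        return math.nan
    value = (
        2.0
        + 9.0 / class_means[2]
        + 1.0 / class_means[3]
        + 5.0 / class_means[4]
        + 3.0 / class_means[6]
    )
    return min(value, cap)


@dataclass
class GenomeProfile:
    """Per-genome aggregate computed on pooled codon counts."""

    genome_id: str
    group: str | None
    n_genes: int
    n_codons: int
    aa: dict[str, float]
    rscu: RscuVector
    gc: PositionalGc
    enc_genomewide: float
    neutrality: "object | None" = None  # NeutralityFit, attached by selection_analysis
    dnc_pct: float | None = None

    @property
    def gc3_genomewide(self) -> float:
        return self.gc.gc3


def genome_profile(
    genes: Sequence[GeneRecord],
    genome_id: str | None = None,
    group: str | None = None,
) -> GenomeProfile:
    """Pool codon counts over all genes and compute genome-wide indices.

    Equivalent to CodonW's ``-totals`` behaviour: indices are computed on the
    pooled counts, never as means of per-gene values.
    """
    if not genes:
        raise ValueError("genome_profile requires at least one gene")
    if genome_id is None:
        genome_id = genes[0].genome_id
    pooled = pooled_counts(genes)
    return GenomeProfile(
        genome_id=genome_id,
        group=group,
        n_genes=len(genes),
        n_codons=pooled.n_codons,
        aa=aa_composition(pooled),
        rscu=rscu(pooled),
        gc=positional_gc_from_counts(pooled),
        enc_genomewide=enc(pooled),
    )


def per_gene_metrics(genes: Sequence[GeneRecord]) -> pd.DataFrame:
    """Per-gene table: gene_id, n_codons, gc1, gc2, gc3, gc12, enc."""
    rows = []
    for gene in genes:
        counts = count_codons(gene.sequence)
        gc = positional_gc_from_counts(counts)
        rows.append(
            {
                "gene_id": gene.gene_id,
                "genome_id": gene.genome_id,
                "n_codons": counts.n_codons,
                "gc1": gc.gc1,
                "gc2": gc.gc2,
                "gc3": gc.gc3,
                "gc12": gc.gc12,
                "enc": enc(counts),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "genome_id", "n_codons", "gc1", "gc2", "gc3", "gc12", "enc"],
    )


def aa_table(profiles: Mapping[str, GenomeProfile]) -> pd.DataFrame:
    """Genomes x 20 amino-acid percentage table."""
    return pd.DataFrame(
        {gid: prof.aa for gid, prof in profiles.items()}
    ).T.loc[:, sorted(FAMILIES)]


def rscu_table(profiles: Mapping[str, GenomeProfile]) -> pd.DataFrame:
    """Genomes x 61 RSCU table (NaN where a family had zero counts)."""
    return pd.DataFrame(
        {gid: prof.rscu.values for gid, prof in profiles.items()}
    ).T.loc[:, list(SENSE_CODONS)]
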