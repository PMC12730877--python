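"""Synthetic multi-genome CDS collections with known mutation/selection structure.

The generator emulates the quantities the analysis pipeline estimates, so every
stage can be verified against ground truth:

* a genome-level mutational GC3 target (``mut_gc3``) with between-gene spread,
  giving each gene its own third-position GC propensity (the x-axis of a
  neutrality plot);
* a linear GC12~GC3 coupling with known slope (``neutrality_slope``), realised
  by tilting the per-gene amino-acid composition toward residues whose codons
  carry the required GC at positions 1-2;
* an optional fraction of genes under codon-level selection, in which the
  preferred codon of each family has its probability multiplied by
  ``sel_strength`` before renormalisation (default preferred set: the
  C-ending, else G-ending, codon of each family, matching the GC-ending
  preference observed in filamentous fungi);
* a companion pure-birth phylogeny with two correlated Brownian-motion traits
  for contrast-based correlation tests.

Within-family codon counts are allocated by largest-remainder rounding of the
target codon distribution ("balanced" mode, the default), with the remainders
assigned at random; a fully multinomial mode is available.  Balanced allocation
pins each gene's realised GC3 and codon distribution to its generating
parameters, which keeps parameter-recovery experiments free of the attenuation
and homozygosity-sampling noise that per-codon multinomial draws would add
(see docs/methods.md).  A single integer seed drives a hierarchical generator
(cohort -> genome -> gene), so per-genome output is reproducible independently
of cohort composition.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .cds_io import GeneRecord, write_cds_fasta
from .genetic_code import FAMILIES, SINGLE_CODON_AAS, START_CODON, STOP_CODONS

#: default amino-acid composition: the near-universal ranking (Ala/Leu/Ser
#: high; Cys/His/Met/Trp low) as a fixed probability vector
DEFAULT_AA_FREQS: dict[str, float] = {
    "A": 0.090, "L": 0.090, "S": 0.080, "G": 0.070, "V": 0.065,
    "T": 0.060, "E": 0.060, "R": 0.055, "P": 0.055, "D": 0.055,
    "K": 0.050, "I": 0.050, "N": 0.040, "Q": 0.040, "F": 0.040,
    "Y": 0.030, "H": 0.022, "M": 0.020, "C": 0.015, "W": 0.013,
}


def default_preferred_codons() -> frozenset[str]:
    """One preferred codon per multi-codon family: C-ending if any, else G-ending."""
    preferred = set()
    for aa, codons in FAMILIES.items():
        if len(codons) == 1:
            continue
        c_ending = [c for c in codons if c.endswith("C")]
        g_ending = [c for c in codons if c.endswith("G")]
        preferred.add((c_ending or g_ending)[0])
    return frozenset(preferred)


@dataclass(frozen=True)
class GenomeSimSpec:
    """Generating parameters for one synthetic genome."""

    genome_id: str
    group: str = "group1"
    n_genes: int = 500
    gene_length_codons: tuple[int, int] = (200, 800)  # sense codons, inclusive
    mut_gc3: float = 0.65
    gc3_spread: float = 0.10  # sd of per-gene GC3 targets (truncated at 2 sd)
    neutrality_slope: float = 1.0
    neutrality_intercept: float | None = None  # default: 0.5 - slope * mut_gc3
    gc12_sigma: float = 0.02
    sel_fraction: float = 0.0
    sel_strength: float = 1.0
    preferred_codons: frozenset[str] = field(default_factory=default_preferred_codons)
    aa_freqs: dict[str, float] | None = None
    codon_sampling: str = "balanced"  # or "multinomial"
    seed: int | None = None

    def validate(self) -> None:
        if not 0.0 <= self.mut_gc3 <= 1.0:
            raise ValueError("mut_gc3 must lie in [0, 1]")
        if not 0.0 <= self.sel_fraction <= 1.0:
            raise ValueError("sel_fraction must lie in [0, 1]")
        if self.sel_strength < 1.0:
            raise ValueError("sel_strength must be >= 1")
        if self.sel_fraction > 0 and self.sel_strength > 1 and not 0.0 < self.mut_gc3 < 1.0:
            raise ValueError(
                "codon selection with a GC-ending preferred set is impossible at "
                f"mut_gc3 = {self.mut_gc3}"
            )
        if self.codon_sampling not in ("balanced", "multinomial"):
            raise ValueError("codon_sampling must be 'balanced' or 'multinomial'")
        lo, hi = self.gene_length_codons
        if lo < 34 or hi < lo:
            raise ValueError("gene_length_codons must satisfy 34 <= lo <= hi")


@dataclass(frozen=True)
class TreeSimSpec:
    n_tips: int = 64
    bm_correlation: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if not -1.0 < self.bm_correlation < 1.0:
            raise ValueError("bm_correlation must lie in (-1, 1)")


@dataclass
class SimulatedGenome:
    spec: GenomeSimSpec
    genes: list[GeneRecord]
    truth: pd.DataFrame  # gene_id, selected, length_codons, gc3_target, gc12_target


# --- precomputed per-family arrays -----------------------------------------

_MULTI_AAS = tuple(aa for aa in sorted(FAMILIES) if len(FAMILIES[aa]) > 1)
_FAMILY_CODONS = {aa: np.asarray(FAMILIES[aa]) for aa in _MULTI_AAS}
_FAMILY_GC_END = {
    aa: np.asarray([c[2] in "GC" for c in FAMILIES[aa]]) for aa in _MULTI_AAS
}
_FAMILY_GC12 = {
    aa: np.asarray([(c[0] in "GC") + (c[1] in "GC") for c in FAMILIES[aa]]) / 2.0
    for aa in _MULTI_AAS
}
_SINGLE_GC_END = {aa: float(FAMILIES[aa][0][2] in "GC") for aa in SINGLE_CODON_AAS}
_SINGLE_GC12 = {
    aa: ((FAMILIES[aa][0][0] in "GC") + (FAMILIES[aa][0][1] in "GC")) / 2.0
    for aa in SINGLE_CODON_AAS
}
_ALL_AAS = tuple(sorted(FAMILIES))


def _family_weights(aa: str, g: float) -> np.ndarray:
    """Neutral within-family codon weights: g on GC-ending, 1-g on AT-ending."""
    gc_end = _FAMILY_GC_END[aa]
    w = np.where(gc_end, g, 1.0 - g)
    total = w.sum()
    if total == 0.0:  # g is exactly 0 or 1 in a family with only one ending type
        w = np.ones_like(w)
        total = w.sum()
    return w / total


def _expected_gc3(aa_probs: np.ndarray, g: float) -> float:
    """Expected per-codon GC3 given amino-acid probabilities and propensity g."""
    total = 0.0
    for aa, p in zip(_ALL_AAS, aa_probs):
        if p == 0.0:
            continue
        if aa in _SINGLE_GC_END:
            total += p * _SINGLE_GC_END[aa]
        else:
            w = _family_weights(aa, g)
            total += p * float(w[_FAMILY_GC_END[aa]].sum())
    return total


def _expected_gc12(base: np.ndarray, t: float, g: float, gc12_vals: np.ndarray) -> float:
    p = base * np.exp(t * gc12_vals)
    p /= p.sum()
    return float(p @ gc12_vals)


def _aa_gc12_values(g: float) -> np.ndarray:
    """Per-amino-acid expected GC fraction at codon positions 1-2 (propensity g)."""
    vals = []
    for aa in _ALL_AAS:
        if aa in _SINGLE_GC12:
            vals.append(_SINGLE_GC12[aa])
        else:
            w = _family_weights(aa, g)
            vals.append(float(w @ _FAMILY_GC12[aa]))
    return np.asarray(vals)


def _solve_monotone(func, target: float, lo: float, hi: float, iters: int = 60) -> float:
    """Bisection for an increasing function; clips targets outside the range."""
    f_lo, f_hi = func(lo), func(hi)
    if target <= f_lo:
        return lo
    if target >= f_hi:
        return hi
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if func(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _balanced_allocation(n: int, probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder integer allocation of n draws over probs."""
    exact = n * probs
    base = np.floor(exact).astype(int)
    remainder = n - int(base.sum())
    if remainder > 0:
        frac = exact - base
        total = frac.sum()
        if total <= 0:
            idx = rng.choice(probs.size, size=remainder, replace=False)
        else:
            idx = rng.choice(probs.size, size=remainder, replace=False, p=frac / total)
        base[idx] += 1
    return base


def _genome_seed(master_seed: int, genome_id: str) -> int:
    digest = hashlib.sha256(f"{master_seed}:{genome_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def simulate_genome(spec: GenomeSimSpec) -> SimulatedGenome:
    """Generate one genome of valid CDS with per-gene ground truth.

    Every emitted gene starts with ATG, ends with a stop codon, contains no
    internal stops, and passes the CDS quality filter by construction.
    """
    spec.validate()
    seed = 0 if spec.seed is None else spec.seed
    gene_seqs = np.random.SeedSequence(seed).spawn(spec.n_genes)
    aa_freqs = dict(DEFAULT_AA_FREQS if spec.aa_freqs is None else spec.aa_freqs)
    base = np.asarray([aa_freqs[aa] for aa in _ALL_AAS], dtype=float)
    base = base / base.sum()
    intercept = (
        0.5 - spec.neutrality_slope * spec.mut_gc3
        if spec.neutrality_intercept is None
        else spec.neutrality_intercept
    )
    lo, hi = spec.gene_length_codons
    preferred = spec.preferred_codons

    genes: list[GeneRecord] = []
    truth_rows = []
    for i, seq_seed in enumerate(gene_seqs):
        rng = np.random.default_rng(seq_seed)
        gene_id = f"{spec.genome_id}_g{i + 1:05d}"
        length = int(rng.integers(lo, hi + 1))  # sense codons incl. the start Met
        selected = bool(rng.random() < spec.sel_fraction)

        # per-gene targets: GC3 spread around mut_gc3; GC12 from the slope relation
        delta = float(rng.normal(0.0, spec.gc3_spread)) if spec.gc3_spread > 0 else 0.0
        delta = float(np.clip(delta, -2.0 * spec.gc3_spread, 2.0 * spec.gc3_spread))
        gc3_target = float(np.clip(spec.mut_gc3 + delta, 0.02, 0.98))
        gc12_target = intercept + spec.neutrality_slope * gc3_target
        if spec.gc12_sigma > 0:
            gc12_target += float(rng.normal(0.0, spec.gc12_sigma))
        gc12_target = float(np.clip(gc12_target, 0.05, 0.95))

        # tilt amino-acid composition so the expected GC12 matches its target
        gc12_vals = _aa_gc12_values(gc3_target)
        t = _solve_monotone(
            lambda t: _expected_gc12(base, t, gc3_target, gc12_vals),
            gc12_target,
            -30.0,
            30.0,
        )
        aa_probs = base * np.exp(t * gc12_vals)
        aa_probs /= aa_probs.sum()

        # adjust the third-base propensity so expected GC3 matches its target
        # (Met/Trp are fixed at GC3=1 and Ile has no G-ending codon, so the
        # neutral propensity is not exactly the realised GC3)
        g = _solve_monotone(
            lambda g: _expected_gc3(aa_probs, g), gc3_target, 0.001, 0.999
        )

        n_free = length - 1  # first codon is the ATG start
        if spec.codon_sampling == "balanced":
            aa_counts = _balanced_allocation(n_free, aa_probs, rng)
        else:
            aa_counts = rng.multinomial(n_free, aa_probs)

        codons: list[str] = []
        for aa, n_aa in zip(_ALL_AAS, aa_counts):
            if n_aa == 0:
                continue
            if aa in _SINGLE_GC_END:
                codons.extend([FAMILIES[aa][0]] * int(n_aa))
                continue
            w = _family_weights(aa, g)
            if selected and spec.sel_strength > 1.0:
                boost = np.asarray(
                    [spec.sel_strength if c in preferred else 1.0 for c in FAMILIES[aa]]
                )
                w = w * boost
                w = w / w.sum()
            if spec.codon_sampling == "balanced":
                codon_counts = _balanced_allocation(int(n_aa), w, rng)
            else:
                codon_counts = rng.multinomial(int(n_aa), w)
            codons.extend(np.repeat(_FAMILY_CODONS[aa], codon_counts).tolist())

        order = rng.permutation(len(codons))
        body = "".join(codons[j] for j in order)
        stop = STOP_CODONS[int(rng.integers(len(STOP_CODONS)))]
        sequence = START_CODON + body + stop
        genes.append(GeneRecord(gene_id, spec.genome_id, sequence, source="cds_fasta"))
        truth_rows.append(
            {
                "gene_id": gene_id,
                "genome_id": spec.genome_id,
                "selected": selected,
                "length_codons": length,
                "gc3_target": gc3_target,
                "gc12_target": gc12_target,
            }
        )
    return SimulatedGenome(spec=spec, genes=genes, truth=pd.DataFrame(truth_rows))


def simulate_cohort(
    specs: Sequence[GenomeSimSpec],
    outdir: str | Path | None = None,
    master_seed: int = 0,
) -> tuple[list[SimulatedGenome], pd.DataFrame, pd.DataFrame]:
    """Simulate several genomes; optionally write FASTA/groups/truth files.

    Specs without a seed get one derived deterministically from
    ``(master_seed, genome_id)``, so a genome's output does not depend on which
    other genomes are in the cohort.  Returns ``(genomes, groups, truth)``.
    """
    if not specs:
        raise ValueError("empty cohort")
    ids = [s.genome_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome_ids in cohort")
    genomes = []
    for spec in specs:
        if spec.seed is None:
            spec = replace(spec, seed=_genome_seed(master_seed, spec.genome_id))
        genomes.append(simulate_genome(spec))
    groups = pd.DataFrame(
        {"genome_id": ids, "group": [s.group for s in specs]}
    )
    truth = pd.concat([g.truth for g in genomes], ignore_index=True)
    params = pd.DataFrame(
        [
            {
                "genome_id": s.genome_id,
                "group": s.group,
                "mut_gc3": s.mut_gc3,
                "neutrality_slope": s.neutrality_slope,
                "sel_fraction": s.sel_fraction,
                "sel_strength": s.sel_strength,
                "seed": g.spec.seed,
            }
            for s, g in zip(specs, genomes)
        ]
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for g in genomes:
            write_cds_fasta(g.genes, outdir / f"{g.spec.genome_id}.fasta")
        groups.to_csv(outdir / "groups.tsv", sep="\t", index=False)
        truth.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        params.to_csv(outdir / "truth_genomes.tsv", sep="\t", index=False)
    return genomes, groups, truth


def _yule_tree(n_tips: int, rng: np.random.Generator) -> dendropy.Tree:
    """Pure-birth (Yule) tree with rate 1: exponential waits between births.

    After the n-th tip appears, one final exponential holding time is added to
    every pending branch, so all branch lengths are strictly positive.
    """
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    active = [tree.seed_node]
    pending = {tree.seed_node: 0.0}
    while len(active) < n_tips:
        wait = rng.exponential(1.0 / len(active))
        for node in active:
            pending[node] += wait
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        parent.edge.length = pending.pop(parent)
        for _ in range(2):
            child = parent.new_child()
            pending[child] = 0.0
            active.append(child)
    wait = rng.exponential(1.0 / len(active))
    for i, node in enumerate(active):
        node.edge.length = pending.pop(node) + wait
        node.taxon = tns.new_taxon(label=f"t{i + 1}")
    tree.seed_node.edge.length = None
    return tree


def simulate_tree_and_traits(spec: TreeSimSpec) -> tuple[str, pd.DataFrame]:
    """Pure-birth tree plus two correlated Brownian-motion traits.

    Returns the newick string (tips ``t1..tn``) and a tip table with columns
    ``genome_id``, ``trait1``, ``trait2``.  Trait increments along each branch
    are bivariate normal with unit rate and correlation ``bm_correlation``.
    """
    spec.validate()
    tree = _yule_tree(spec.n_tips, np.random.default_rng(np.random.SeedSequence([spec.seed, 0])))
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    rho = spec.bm_correlation
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)
    values: dict[dendropy.Node, np.ndarray] = {}
    rows = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = np.zeros(2)
        else:
            bl = node.edge.length or 0.0
            step = chol @ rng.standard_normal(2) * np.sqrt(bl)
            values[node] = values[node.parent_node] + step
        if node.is_leaf():
            v = values[node]
            rows.append(
                {"genome_id": node.taxon.label, "trait1": v[0], "trait2": v[1]}
            )
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    return newick, pd.DataFrame(rows)
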