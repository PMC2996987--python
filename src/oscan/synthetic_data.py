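"""Synthetic genomes with controlled composition for pipeline testing.

Genomes are sets of stop-free CDS drawn from a codon-usage model whose G+C
content is set by exponential tilting: sense-codon frequencies are
reweighted by exp(lambda * gc(codon)) with lambda solved so the expected
coding G+C hits the target. A dicodon-level OSC excess can be planted by
multiplying transition probabilities into OSC-forming codon pairs by
(1 + epsilon), mirroring selection on codon pairs at junctions, which the
analytic dicodon oracle can score exactly.
"""
from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import _encoding as enc
from .genome_io import CodingSequence, GeneticCode, GenomeCDSSet
from .markov_models import (
    CodonBasedModel,
    PeriodicMarkovModel,
    generate_cds_encoded,
    generate_codons,
)


@dataclasses.dataclass
class SynthesisSpec:
    n_genes: int
    gc_target: float | None = 0.5
    table_id: int = 11
    seed: int = 0
    length_sampler: object = 300  # int, sequence of ints, or callable(rng, n)
    base_model: object | None = None
    osc_excess_epsilon: float = 0.0
    organism: str | None = None
    genus: str | None = None

    def lengths(self, rng: np.random.Generator) -> np.ndarray:
        ls = self.length_sampler
        if callable(ls):
            lengths = np.asarray(ls(rng, self.n_genes), dtype=np.int64)
        elif np.isscalar(ls):
            lengths = np.full(self.n_genes, int(ls), dtype=np.int64)
        else:
            lengths = np.asarray(ls, dtype=np.int64)
            if lengths.size != self.n_genes:
                raise ValueError("length list size != n_genes")
        if (lengths < 100).any():
            raise ValueError("gene lengths must be >= 100 codons to pass filters")
        return lengths


def lognormal_lengths(median: float = 300.0, sigma: float = 0.4) -> Callable:
    """Length sampler: lognormal codon counts clipped at 100."""
    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return np.maximum(
            100, np.round(rng.lognormal(np.log(median), sigma, size=n))).astype(np.int64)
    return sample


def _codon_gc_counts() -> np.ndarray:
    counts = np.zeros(64)
    for i, codon in enumerate(enc.ALL_CODONS):
        counts[i] = codon.count("G") + codon.count("C")
    return counts


def tilt_codon_freq(base_freq: np.ndarray, gc_target: float,
                    tol: float = 1e-4) -> np.ndarray:
    """Exponentially tilt codon frequencies to a target coding G+C fraction."""
    if not 0 < gc_target < 1:
        raise ValueError("gc_target must be in (0, 1)")
    gc = _codon_gc_counts()
    support = base_freq > 0

    def expected_gc(lam: float) -> float:
        w = np.where(support, base_freq * np.exp(lam * gc), 0.0)
        w /= w.sum()
        return float((w * gc).sum() / 3.0)

    lo, hi = expected_gc(-60.0), expected_gc(60.0)
    if not lo + tol / 10 < gc_target < hi - tol / 10:
        raise ValueError(
            f"gc_target {gc_target} infeasible for this codon support "
            f"(attainable range ~[{lo:.4f}, {hi:.4f}])")
    lam = brentq(lambda l: expected_gc(l) - gc_target, -60.0, 60.0, xtol=1e-10)
    w = np.where(support, base_freq * np.exp(lam * gc), 0.0)
    w /= w.sum()
    assert abs(float((w * gc).sum() / 3.0) - gc_target) < tol
    return w


def uniform_sense_freq(table_id: int) -> np.ndarray:
    stops = GeneticCode.from_table_id(table_id).stop_codons
    freq = np.array([0.0 if c in stops else 1.0 for c in enc.ALL_CODONS])
    return freq / freq.sum()


def plant_osc_excess(model: CodonBasedModel, epsilon: float) -> CodonBasedModel:
    """Reweight dicodon transitions into OSC-forming codon pairs by (1+epsilon).

    Rows are renormalized; epsilon = -1 removes OSC-forming junctions
    entirely, epsilon = 0 returns an equivalent model.
    """
    if model.kind != "dicodon":
        raise ValueError("OSC excess is planted on a dicodon model")
    if epsilon < -1:
        raise ValueError("epsilon must be >= -1")
    t2, t3 = enc.junction_osc_tables(model.stops)
    forms_osc = t2 | t3
    T = model.dicodon_trans * np.where(forms_osc, 1.0 + epsilon, 1.0)
    sums = T.sum(axis=1, keepdims=True)
    T = np.where(sums > 0, T / np.maximum(sums, 1e-300), 0.0)
    return dataclasses.replace(model, dicodon_trans=T)


def dicodon_from_codon_usage(freq: np.ndarray, table_id: int) -> CodonBasedModel:
    """The dicodon chain whose every row equals the codon-usage marginal."""
    T = np.tile(freq, (64, 1))
    T[freq == 0, :] = 0.0
    return CodonBasedModel(kind="dicodon", table_id=table_id, codon_freq=freq,
                           dicodon_trans=T)


def synth_genome(spec: SynthesisSpec) -> GenomeCDSSet:
    """Generate a stop-free synthetic genome from a SynthesisSpec.

    With no base model, genes are i.i.d. sense codons at the tilted
    frequencies; a planted OSC excess switches generation to the reweighted
    dicodon chain. A supplied base model is used as-is (codon-based models
    may additionally be tilted/planted; periodic models cannot be
    retargeted, so gc_target must then be None).
    """
    rng = np.random.default_rng(spec.seed)
    model = spec.base_model
    if isinstance(model, PeriodicMarkovModel):
        if spec.gc_target is not None:
            raise ValueError("gc_target cannot be imposed on a periodic base model")
        if spec.osc_excess_epsilon:
            raise ValueError("OSC excess planting requires a codon-based model")
        gen = lambda L: enc.codons_from_nt(generate_cds_encoded(model, int(L), rng))
    else:
        if model is None:
            freq = uniform_sense_freq(spec.table_id)
        else:
            freq = model.codon_freq.copy()
        if spec.gc_target is not None:
            freq = tilt_codon_freq(freq, spec.gc_target)
        if spec.osc_excess_epsilon:
            base = (model if model is not None and model.kind == "dicodon"
                    else dicodon_from_codon_usage(freq, spec.table_id))
            chain = plant_osc_excess(base, spec.osc_excess_epsilon)
            gen = lambda L: generate_codons(chain, int(L), rng)
        elif model is not None and model.kind != "codon_usage":
            gen = lambda L: generate_codons(model, int(L), rng)
        else:
            usage = CodonBasedModel(kind="codon_usage", table_id=spec.table_id,
                                    codon_freq=freq)
            gen = lambda L: generate_codons(usage, int(L), rng)
    lengths = spec.lengths(rng)
    name = spec.organism or (
        f"synth_t{spec.table_id}_gc{spec.gc_target if spec.gc_target is not None else 'NA'}"
        f"_seed{spec.seed}")
    cds = []
    for i, L in enumerate(lengths):
        codons = gen(L)
        cds.append(CodingSequence(
            id=f"{name}_g{i:05d}", organism=name,
            sequence=enc.decode_seq(enc.nt_from_codons(codons)),
            genetic_code=spec.table_id))
    return GenomeCDSSet(organism=name, genus=spec.genus or name, division="synthetic",
                        genetic_code=spec.table_id, cds=cds)


def synth_ogt_dataset(n_genomes: int, planted_slope: float, seed: int = 0,
                      noise_sd: float = 0.3) -> pd.DataFrame:
    """Synthetic (pct_deviation, ogt, gc, at_skew) table for the OGT analysis.

    Covariates: gc ~ U(0.25, 0.75), at_skew ~ U(-0.2, 0.2), ogt drawn from
    the category midpoints {10, 37, 60, 85} degC. Response:
    0.5 + planted_slope*ogt + 2*(gc - 0.5) + at_skew + N(0, noise_sd).
    """
    if n_genomes < 10:
        raise ValueError("need at least 10 genomes")
    rng = np.random.default_rng(seed)
    gc = rng.uniform(0.25, 0.75, n_genomes)
    at_skew = rng.uniform(-0.2, 0.2, n_genomes)
    ogt = rng.choice([10.0, 37.0, 60.0, 85.0], size=n_genomes)
    pct = (0.5 + planted_slope * ogt + 2.0 * (gc - 0.5) + at_skew
           + rng.normal(0.0, noise_sd, n_genomes))
    return pd.DataFrame({"pct_deviation": pct, "ogt": ogt, "gc": gc,
                         "at_skew": at_skew})


def write_genome(genome: GenomeCDSSet, fasta_path, manifest_path=None) -> None:
    """Write a genome as FASTA (+ optional single-row manifest TSV)."""
    from .genome_io import MANIFEST_COLUMNS, write_fasta

    write_fasta(genome.cds, fasta_path)
    if manifest_path is not None:
        row = {"path": str(fasta_path), "format": "fasta",
               "organism": genome.organism, "genus": genome.genus,
               "division": genome.division, "table_id": genome.genetic_code,
               "ogt_category": genome.ogt_category or "",
               "ogt_celsius": genome.ogt_celsius if genome.ogt_celsius is not None else ""}
        pd.DataFrame([row], columns=MANIFEST_COLUMNS).to_csv(
            manifest_path, sep="\t", index=False)
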