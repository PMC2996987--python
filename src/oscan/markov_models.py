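"""Nested composition models of coding sequence and random-gene generation.

Two families are implemented, forming a nesting from simplest to richest:

* codon-based chains — ``codon_usage`` (i.i.d. sense codons), ``dipeptide``
  (first-order chain over amino acids with genome-wide synonymous choice)
  and ``dicodon`` (first-order chain over codons);
* phase-aware (three-periodic) nucleotide chains of order m, where the
  transition table for a position depends on its codon phase (0-based
  index mod 3). Orders 2 and 5 capture trinucleotide and hexanucleotide
  bias respectively.

All models are maximum-likelihood fits with zero pseudocounts, so a chain
trained on stop-free genes assigns probability zero to any in-frame stop
codon; generation additionally masks stop-completing emissions explicitly
at every back-off order, guaranteeing stop-free output.
"""
from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np

from . import _encoding as enc
from .genome_io import GeneticCode, GenomeCDSSet


# --------------------------------------------------------------------------
# three-periodic nucleotide Markov models
# --------------------------------------------------------------------------

class PeriodicMarkovModel:
    """Phase-aware nucleotide Markov chain of order ``m``.

    ``counts[p, ctx, x]`` is the number of training positions with codon
    phase ``p``, previous-``m``-nt context ``ctx`` (base-4 code, oldest
    digit most significant) and next nucleotide ``x``. Rows are resolved to
    probabilities at build time: an unseen context backs off to the longest
    shorter context with data at the same phase, and every phase-2 row is
    masked so that no emission can complete an in-frame stop codon of the
    model's genetic code.
    """

    def __init__(self, order: int, counts: np.ndarray, initial_counts: np.ndarray,
                 table_id: int):
        if order < 1:
            raise ValueError("order must be >= 1")
        self.order = order
        self.table_id = table_id
        self.counts = counts          # (3, 4**m, 4) int64
        self.initial_counts = initial_counts  # (4**m,) int64
        self._resolve()

    # -- construction ------------------------------------------------------

    def _resolve(self) -> None:
        m = self.order
        n_ctx = 4 ** m
        stops = enc.stop_indices(GeneticCode.from_table_id(self.table_id).stop_codons)
        stop_set = set(int(s) for s in stops)
        # marginal count tables for back-off orders m-1 .. 0
        marg = {m: self.counts}
        for k in range(m - 1, -1, -1):
            marg[k] = marg[k + 1].reshape(3, 4, -1, 4).sum(axis=1)
        probs = np.zeros((3, n_ctx, 4))
        self.backoff_order = np.full((3, n_ctx), -1, dtype=np.int8)
        for p in range(3):
            for ctx in range(n_ctx):
                row = None
                for k in range(m, -1, -1):
                    ck = ctx % (4 ** k)
                    r = marg[k][p, ck]
                    if r.sum() > 0:
                        row = r.astype(float)
                        self.backoff_order[p, ctx] = k
                        break
                if row is None:
                    row = np.ones(4)
                if p == 2 and m >= 2:
                    prefix = ctx % 16  # last two context nt = phases 0,1
                    allowed = np.array([prefix * 4 + x not in stop_set for x in range(4)])
                    row = np.where(allowed, row, 0.0)
                    if row.sum() == 0:
                        row = allowed.astype(float)
                s = row.sum()
                probs[p, ctx] = row / s
        self.probs = probs
        self._cum = np.cumsum(probs, axis=2)
        ini = self.initial_counts.astype(float)
        if ini.sum() == 0:
            raise ValueError("model has no initial-context distribution")
        self._ini_cum = np.cumsum(ini / ini.sum())
        self._stop_set = stop_set

    def transition_prob(self, context: str, nxt: str, phase: int) -> float:
        """P(next nt | previous ``order`` nt, phase of the next position)."""
        ctx = 0
        for ch in context.upper():
            ctx = ctx * 4 + enc.NT.index(ch)
        return float(self.probs[phase, ctx, enc.NT.index(nxt.upper())])

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "order": self.order, "table_id": self.table_id,
            "counts": self.counts.tolist(),
            "initial_counts": self.initial_counts.tolist(),
        })

    @classmethod
    def from_json(cls, s: str) -> "PeriodicMarkovModel":
        d = json.loads(s)
        return cls(d["order"], np.array(d["counts"], dtype=np.int64),
                   np.array(d["initial_counts"], dtype=np.int64), d["table_id"])


def train_periodic_markov(genome: GenomeCDSSet, order: int) -> PeriodicMarkovModel:
    """Fit a three-periodic order-``order`` model to a genome's CDS set."""
    if order < 1:
        raise ValueError("order must be >= 1")
    if not genome.cds:
        raise ValueError("cannot train on an empty genome")
    m = order
    n_ctx = 4 ** m
    counts = np.zeros((3, n_ctx, 4), dtype=np.int64)
    initial = np.zeros(n_ctx, dtype=np.int64)
    powers = 4 ** np.arange(m - 1, -1, -1, dtype=np.int64)
    total_nt = 0
    for c in genome.cds:
        s = enc.encode_seq(c.sequence).astype(np.int64)
        total_nt += s.size
        if s.size <= m:
            continue
        win = np.lib.stride_tricks.sliding_window_view(s, m)[:-1]  # contexts
        ctx = win @ powers
        nxt = s[m:]
        phase = np.arange(m, s.size) % 3
        np.add.at(counts, (phase, ctx, nxt), 1)
        initial[int(s[:m] @ powers)] += 1
    if total_nt < 4 ** (order + 1):
        warnings.warn(
            f"only {total_nt} training nt for order {order} "
            f"(4^{order + 1} = {4 ** (order + 1)} recommended)", stacklevel=2)
    return PeriodicMarkovModel(order, counts, initial, genome.genetic_code)


def generate_cds(model: PeriodicMarkovModel, n_codons: int,
                 rng: np.random.Generator) -> str:
    """Sample one stop-free gene of ``n_codons`` codons from the model."""
    return enc.decode_seq(generate_cds_encoded(model, n_codons, rng))


def generate_cds_encoded(model: PeriodicMarkovModel, n_codons: int,
                         rng: np.random.Generator) -> np.ndarray:
    m = model.order
    length = 3 * n_codons
    if length < m:
        raise ValueError(f"n_codons too small for order {m}")
    out = np.empty(length, dtype=np.uint8)
    # initial m-mer from the empirical gene-start distribution
    code = int(np.searchsorted(model._ini_cum, rng.random(), side="right"))
    for j in range(m - 1, -1, -1):
        out[j] = code % 4
        code //= 4
    ctx = int(out[:m] @ (4 ** np.arange(m - 1, -1, -1)))
    mask = 4 ** m
    # plain-python tables are much faster than numpy scalar indexing here
    cum = model._cum.tolist()
    stop_set = model._stop_set
    u = rng.random(length - m).tolist()  # python floats: int-summable comparisons
    seq = out.tolist()
    for i in range(m, length):
        row = cum[i % 3][ctx]
        x = u[i - m]
        nt = (x > row[0]) + (x > row[1]) + (x > row[2])
        if i % 3 == 2:  # phase 2: never complete an in-frame stop
            codon_prefix = 16 * seq[i - 2] + 4 * seq[i - 1]
            if codon_prefix + nt in stop_set:
                probs = model.probs[2, ctx].copy()
                for cand in range(4):
                    if codon_prefix + cand in stop_set:
                        probs[cand] = 0.0
                if probs.sum() == 0:
                    probs = np.array([codon_prefix + cand not in stop_set
                                      for cand in range(4)], dtype=float)
                probs /= probs.sum()
                nt = int(rng.choice(4, p=probs))
        seq[i] = nt
        ctx = (ctx * 4 + nt) % mask
    return np.array(seq, dtype=np.uint8)


# --------------------------------------------------------------------------
# codon-based models
# --------------------------------------------------------------------------

AA_RESTART = "restart"  # policy marker for dead-end chains


@dataclasses.dataclass
class CodonBasedModel:
    """Codon-level chain: i.i.d. codon usage, dicodon chain, or dipeptide chain.

    ``codon_freq`` is a length-64 distribution supported on sense codons and
    doubles as the initial-codon distribution of the chain variants.
    """

    kind: str  # codon_usage | dicodon | dipeptide
    table_id: int
    codon_freq: np.ndarray                      # (64,)
    dicodon_trans: np.ndarray | None = None     # (64, 64), rows sum to 1 or 0
    aa_list: tuple[str, ...] | None = None
    aa_trans: np.ndarray | None = None          # (n_aa, n_aa)
    codon_given_aa: np.ndarray | None = None    # (n_aa, 64)

    def __post_init__(self):
        if self.kind not in ("codon_usage", "dicodon", "dipeptide"):
            raise ValueError(f"unknown model kind {self.kind!r}")

    @property
    def stops(self) -> frozenset[str]:
        return GeneticCode.from_table_id(self.table_id).stop_codons

    def to_json(self) -> str:
        d = {"kind": self.kind, "table_id": self.table_id,
             "codon_freq": self.codon_freq.tolist()}
        if self.dicodon_trans is not None:
            d["dicodon_trans"] = self.dicodon_trans.tolist()
        if self.aa_trans is not None:
            d["aa_list"] = list(self.aa_list)
            d["aa_trans"] = self.aa_trans.tolist()
            d["codon_given_aa"] = self.codon_given_aa.tolist()
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "CodonBasedModel":
        d = json.loads(s)
        return cls(
            kind=d["kind"], table_id=d["table_id"],
            codon_freq=np.array(d["codon_freq"]),
            dicodon_trans=np.array(d["dicodon_trans"]) if "dicodon_trans" in d else None,
            aa_list=tuple(d["aa_list"]) if "aa_list" in d else None,
            aa_trans=np.array(d["aa_trans"]) if "aa_trans" in d else None,
            codon_given_aa=np.array(d["codon_given_aa"]) if "codon_given_aa" in d else None,
        )


def _normalize_rows(counts: np.ndarray) -> np.ndarray:
    sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sums > 0, counts / np.maximum(sums, 1e-300), 0.0)
    return out


def train_codon_based(genome: GenomeCDSSet, kind: str) -> CodonBasedModel:
    """ML fit of a codon-usage, dicodon or dipeptide model to a CDS set."""
    if kind not in ("codon_usage", "dicodon", "dipeptide"):
        raise ValueError(f"unknown model kind {kind!r}")
    if not genome.cds:
        raise ValueError("cannot train on an empty genome")
    code = genome.code
    counts = np.zeros(64, dtype=np.int64)
    genes_codons = []
    for c in genome.cds:
        cod = enc.codons_from_nt(enc.encode_seq(c.sequence))
        genes_codons.append(cod)
        counts += np.bincount(cod, minlength=64)
    freq = counts / counts.sum()
    model = CodonBasedModel(kind=kind, table_id=genome.genetic_code, codon_freq=freq)
    if kind == "dicodon":
        dc = np.zeros((64, 64), dtype=np.int64)
        for cod in genes_codons:
            np.add.at(dc, (cod[:-1], cod[1:]), 1)
        model.dicodon_trans = _normalize_rows(dc)
    elif kind == "dipeptide":
        aa_list = tuple(sorted({code.translate(enc.codon_str(i))
                                for i in range(64) if counts[i] > 0}))
        aa_idx = {a: i for i, a in enumerate(aa_list)}
        codon_aa = np.full(64, -1, dtype=np.int64)
        for i in range(64):
            s = enc.codon_str(i)
            if s not in code.stop_codons:
                a = code.translate(s)
                if a in aa_idx:
                    codon_aa[i] = aa_idx[a]
        at = np.zeros((len(aa_list), len(aa_list)), dtype=np.int64)
        cga = np.zeros((len(aa_list), 64), dtype=np.int64)
        for cod in genes_codons:
            aas = codon_aa[cod]
            np.add.at(at, (aas[:-1], aas[1:]), 1)
            np.add.at(cga, (aas, cod), 1)
        model.aa_list = aa_list
        model.aa_trans = _normalize_rows(at)
        model.codon_given_aa = _normalize_rows(cga)
    return model


def generate_codons(model: CodonBasedModel, n_codons: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Sample ``n_codons`` sense codons (as indices) from the model."""
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if model.kind == "codon_usage":
        cum = np.cumsum(model.codon_freq)
        return np.searchsorted(cum, rng.random(n_codons) * cum[-1], side="right")
    if model.kind == "dicodon":
        cum0 = np.cumsum(model.codon_freq)
        cum = np.cumsum(model.dicodon_trans, axis=1)
        rowsum = model.dicodon_trans.sum(axis=1)
        out = np.empty(n_codons, dtype=np.int64)
        u = rng.random(n_codons)
        c = int(np.searchsorted(cum0, u[0] * cum0[-1], side="right"))
        out[0] = c
        for j in range(1, n_codons):
            if rowsum[c] <= 0:  # dead end: restart from marginal usage
                c = int(np.searchsorted(cum0, u[j] * cum0[-1], side="right"))
            else:
                c = int(np.searchsorted(cum[c], u[j] * cum[c][-1], side="right"))
            out[j] = c
        return out
    # dipeptide: amino-acid chain, then genome-wide synonymous codon choice;
    # initial aa from the codon marginal
    aa_of_codon = np.argmax(model.codon_given_aa > 0, axis=0)
    aa0 = np.zeros(len(model.aa_list))
    for c in range(64):
        if model.codon_freq[c] > 0:
            aa0[aa_of_codon[c]] += model.codon_freq[c]
    aa0 /= aa0.sum()
    cum_aa0 = np.cumsum(aa0)
    cum_at = np.cumsum(model.aa_trans, axis=1)
    at_rowsum = model.aa_trans.sum(axis=1)
    u = rng.random(n_codons)
    aas = np.empty(n_codons, dtype=np.int64)
    a = int(np.searchsorted(cum_aa0, u[0] * cum_aa0[-1], side="right"))
    aas[0] = a
    for j in range(1, n_codons):
        if at_rowsum[a] <= 0:
            a = int(np.searchsorted(cum_aa0, u[j] * cum_aa0[-1], side="right"))
        else:
            a = int(np.searchsorted(cum_at[a], u[j] * cum_at[a][-1], side="right"))
        aas[j] = a
    cum_cga = np.cumsum(model.codon_given_aa, axis=1)
    v = rng.random(n_codons)
    out = np.empty(n_codons, dtype=np.int64)
    for j in range(n_codons):
        row = cum_cga[aas[j]]
        out[j] = np.searchsorted(row, v[j] * row[-1], side="right")
    return out


def generate_cds_codon_based(model: CodonBasedModel, n_codons: int,
                             rng: np.random.Generator) -> str:
    return enc.decode_seq(enc.nt_from_codons(generate_codons(model, n_codons, rng)))


# --------------------------------------------------------------------------
# analytic expectations (oracles for the Monte Carlo machinery)
# --------------------------------------------------------------------------

def analytic_osc_expectation(model: CodonBasedModel, n_codons: int,
                             stop_codons=None):
    """Exact expected OSC counts (frame +2, frame +3) for an i.i.d. codon model.

    Every shifted-frame window spans exactly one junction of adjacent
    codons, so E[N_f] = (n_codons - 1) * p_f with p_f the per-junction OSC
    probability, computed by brute-force enumeration over all codon pairs.
    """
    if model.kind != "codon_usage":
        raise ValueError("analytic expectation requires an i.i.d. codon_usage model")
    if stop_codons is None:
        stop_codons = model.stops
    stops = set(s.upper() for s in stop_codons)
    f = model.codon_freq
    p2 = p3 = 0.0
    for c1 in range(64):
        if f[c1] == 0:
            continue
        s1 = enc.codon_str(c1)
        for c2 in range(64):
            if f[c2] == 0:
                continue
            s2 = enc.codon_str(c2)
            w = f[c1] * f[c2]
            if s1[1:] + s2[0] in stops:
                p2 += w
            if s1[2] + s2[:2] in stops:
                p3 += w
    return (n_codons - 1) * p2, (n_codons - 1) * p3


def analytic_osc_expectation_dicodon(model: CodonBasedModel, n_codons: int,
                                     tol: float = 1e-14):
    """Expected OSC counts (frame +2, frame +3) under a dicodon chain.

    Propagates the exact codon marginal along the chain from the initial
    distribution (``codon_freq``); once the marginal converges the remaining
    junctions are scored at the limiting distribution.
    """
    if model.kind != "dicodon":
        raise ValueError("requires a dicodon model")
    t2, t3 = enc.junction_osc_tables(model.stops)
    T = model.dicodon_trans
    v2 = (T * t2).sum(axis=1)  # P(junction OSC in +2 | current codon)
    v3 = (T * t3).sum(axis=1)
    m = model.codon_freq.copy()
    e2 = e3 = 0.0
    for j in range(n_codons - 1):
        e2 += float(m @ v2)
        e3 += float(m @ v3)
        m_next = m @ T
        # dead-end rows lose mass; restart policy refills from codon_freq
        lost = 1.0 - m_next.sum()
        if lost > 1e-15:
            m_next = m_next + lost * model.codon_freq
        if np.abs(m_next - m).max() < tol:
            rest = n_codons - 2 - j
            e2 += rest * float(m_next @ v2)
            e3 += rest * float(m_next @ v3)
            return e2, e3
        m = m_next
    return e2, e3
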