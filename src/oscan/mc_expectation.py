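"""Monte Carlo estimation of expected OSC frequencies and significance tests.

For each genome a composition model is trained on its own CDS set; each
trial generates a full synthetic genome with the identical multiset of gene
lengths, and the per-trial OSC densities (per 100 codons) form the null
sample. The observed density is compared to that sample with a one-sample
t-test (simulated values as the sample, observed density as the reference
constant), two-tailed, with Benjamini-Hochberg FDR control across genomes
within each (model, frame) family.

The one-sample t statistic scales the observed-vs-mean gap by the standard
error of the simulated mean, SD/sqrt(n_trials). Because the observed genome
is itself one realisation of the same generative scale, this statistic is
sensitive but anticonservative as a pure significance measure; the
``p_pred`` field carries the calibrated alternative that treats the
observed density as a single draw from the trial distribution
(prediction-interval t-test). Directions and q-values follow the primary
t-test.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import _encoding as enc
from .genome_io import GenomeCDSSet
from .markov_models import (
    CodonBasedModel,
    PeriodicMarkovModel,
    generate_cds_encoded,
    generate_codons,
    train_codon_based,
    train_periodic_markov,
)
from .osc_metrics import genome_osc_stats

MODEL_SPECS = ("periodic2", "periodic5", "codon_usage", "dicodon", "dipeptide")
_ALIASES = {"codon": "codon_usage", "periodic m=2": "periodic2",
            "periodic m=5": "periodic5"}
FRAMES = ("+2", "+3", "both")


@dataclasses.dataclass
class FrameStats:
    frame: str
    observed: float
    mean_expected: float
    sd_expected: float
    t_stat: float
    p_value: float
    q_value: float
    pct_deviation: float
    direction: str  # over | under | ns
    p_pred: float
    degenerate: bool = False


@dataclasses.dataclass
class ExpectationResult:
    organism: str
    model_id: str
    n_trials: int
    sim_densities: dict[str, np.ndarray]  # frame -> per-trial densities
    frames: dict[str, FrameStats]

    def frame(self, frame: str) -> FrameStats:
        return self.frames[frame]


def one_sample_t_test(values, reference: float):
    """Two-tailed one-sample t-test of ``values`` against ``reference``.

    Returns (t, p). A zero-variance sample equal to the reference gives
    (0, 1); zero variance away from the reference gives (inf-signed t, 0).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    sd = values.std(ddof=1)
    if sd == 0:
        if values.mean() == reference:
            return 0.0, 1.0
        return math.copysign(math.inf, values.mean() - reference), 0.0
    t, p = sps.ttest_1samp(values, popmean=reference)
    return float(t), float(p)


def bh_adjust(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg step-up adjustment; returns (q_values, rejected).

    ``rejected`` flags q < alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, q < alpha


def _trial_rng(seed: int, trial: int) -> np.random.Generator:
    # Mersenne-Twister stream per (master seed, trial)
    return np.random.Generator(np.random.MT19937(np.random.SeedSequence((seed, trial))))


def _train(genome: GenomeCDSSet, model_spec: str):
    spec = _ALIASES.get(model_spec, model_spec)
    if spec == "periodic2":
        return train_periodic_markov(genome, 2)
    if spec == "periodic5":
        return train_periodic_markov(genome, 5)
    if spec in ("codon_usage", "dicodon", "dipeptide"):
        return train_codon_based(genome, spec)
    raise ValueError(f"unknown model spec {model_spec!r}; choose from {MODEL_SPECS}")


def _trial_densities(model, lengths: np.ndarray, t2, t3, rng) -> tuple[float, float]:
    """Generate one synthetic genome and return (density2, density3)."""
    total = int(lengths.sum())
    if isinstance(model, CodonBasedModel):
        if model.kind == "codon_usage":
            codons = generate_codons(model, total, rng)
        else:
            codons = np.concatenate(
                [generate_codons(model, int(L), rng) for L in lengths])
    else:
        codons = np.concatenate(
            [enc.codons_from_nt(generate_cds_encoded(model, int(L), rng))
             for L in lengths])
    n2, n3 = enc.count_oscs_codon_genes(codons, lengths, t2, t3)
    return 100.0 * n2 / total, 100.0 * n3 / total


def _frame_stats(frame: str, sims: np.ndarray, observed: float,
                 alpha: float) -> FrameStats:
    mean = float(sims.mean())
    sd = float(sims.std(ddof=1))
    t, p = one_sample_t_test(sims, observed)
    degenerate = sd == 0 and mean != observed
    pct = 100.0 * (observed - mean) / mean if mean != 0 else math.nan
    n = sims.size
    if sd > 0:
        z = (observed - mean) / (sd * math.sqrt(1.0 + 1.0 / n))
        p_pred = float(2 * sps.t.sf(abs(z), df=n - 1))
    else:
        p_pred = 1.0 if observed == mean else 0.0
    fs = FrameStats(frame=frame, observed=observed, mean_expected=mean,
                    sd_expected=sd, t_stat=t, p_value=p, q_value=p,
                    pct_deviation=pct, direction="ns", p_pred=p_pred,
                    degenerate=degenerate)
    _set_direction(fs, alpha)
    return fs


def _set_direction(fs: FrameStats, alpha: float) -> None:
    if fs.q_value < alpha and fs.observed > fs.mean_expected:
        fs.direction = "over"
    elif fs.q_value < alpha and fs.observed < fs.mean_expected:
        fs.direction = "under"
    else:
        fs.direction = "ns"


def run_expectation(genome: GenomeCDSSet, model_spec: str, n_trials: int = 200,
                    seed: int = 0, frames: str = "both",
                    alpha: float = 0.05) -> ExpectationResult:
    """Monte Carlo expected-OSC analysis of one genome under one model.

    The model is trained on the genome's own CDS; ``n_trials`` synthetic
    genomes matching its gene-length multiset are generated and scored, and
    the observed density is tested against the simulated sample. Without a
    batch-level FDR correction q defaults to the raw p.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    if frames not in FRAMES:
        raise ValueError(f"frames must be one of {FRAMES}")
    model = _train(genome, model_spec)
    obs = genome_osc_stats(genome)
    lengths = np.array([c.n_codons for c in genome.cds], dtype=np.int64)
    t2, t3 = enc.junction_osc_tables(genome.code.stop_codons)
    sim2 = np.empty(n_trials)
    sim3 = np.empty(n_trials)
    for trial in range(n_trials):
        d2, d3 = _trial_densities(model, lengths, t2, t3, _trial_rng(seed, trial))
        sim2[trial] = d2
        sim3[trial] = d3
    sims = {"+2": sim2, "+3": sim3, "both": sim2 + sim3}
    observed = {"+2": obs.density2, "+3": obs.density3, "both": obs.density_total}
    wanted = ("+2", "+3", "both") if frames == "both" else (frames,)
    frame_stats = {f: _frame_stats(f, sims[f], observed[f], alpha) for f in wanted}
    return ExpectationResult(
        organism=genome.organism, model_id=_ALIASES.get(model_spec, model_spec),
        n_trials=n_trials, sim_densities={f: sims[f] for f in wanted},
        frames=frame_stats)


def batch_analysis(genomes, model_specs, n_trials: int = 200, seed: int = 0,
                   alpha: float = 0.05, frames: str = "both"):
    """Expectation analysis over a genome cohort with per-(model, frame) FDR.

    Returns (results table as DataFrame, summary dict, list of
    ExpectationResult, failures dict). Per-genome failures are recorded and
    the batch continues.
    """
    genomes = list(genomes)
    if not genomes:
        raise ValueError("no genomes given")
    if isinstance(model_specs, str):
        model_specs = [model_specs]
    results: list[ExpectationResult] = []
    failures: dict[str, str] = {}
    for gi, genome in enumerate(genomes):
        for mi, spec in enumerate(model_specs):
            sub_seed = int(np.random.SeedSequence((seed, gi, mi)).generate_state(1)[0])
            try:
                results.append(run_expectation(
                    genome, spec, n_trials=n_trials, seed=sub_seed,
                    frames=frames, alpha=alpha))
            except (ValueError, KeyError) as exc:
                failures[f"{genome.organism}/{spec}"] = str(exc)
    # BH within each (model, frame) family across genomes
    by_family: dict[tuple[str, str], list[FrameStats]] = {}
    for res in results:
        for f, fs in res.frames.items():
            by_family.setdefault((res.model_id, f), []).append(fs)
    for (_, _), fss in by_family.items():
        q, _ = bh_adjust([fs.p_value for fs in fss], alpha)
        for fs, qv in zip(fss, q):
            fs.q_value = float(qv)
            _set_direction(fs, alpha)
    rows = []
    for res in results:
        for f, fs in res.frames.items():
            rows.append({
                "organism": res.organism, "model": res.model_id, "frame": f,
                "n_trials": res.n_trials, "observed": fs.observed,
                "mean_expected": fs.mean_expected, "sd_expected": fs.sd_expected,
                "t": fs.t_stat, "p": fs.p_value, "q": fs.q_value,
                "p_pred": fs.p_pred, "pct_deviation": fs.pct_deviation,
                "direction": fs.direction,
            })
    table = pd.DataFrame(rows)
    summary = {}
    for (model, frame), fss in sorted(by_family.items()):
        tally = {"over": 0, "under": 0, "ns": 0}
        for fs in fss:
            tally[fs.direction] += 1
        summary[f"{model}|{frame}"] = tally
    return table, summary, results, failures
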