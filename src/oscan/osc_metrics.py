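"""Per-gene and per-genome OSC counts, densities, usage bias and composition.

An out-of-frame stop codon (OSC) is a stop trinucleotide read in one of the
two shifted frames of a coding sequence: frame +2 starts one nucleotide into
the annotated frame (the frame seen after a +1 ribosomal frameshift), frame
+3 two nucleotides in (-1 frameshift). Frames are scanned as non-overlapping
triplets within a single CDS; no window spans a gene boundary.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from . import _encoding as enc
from .genome_io import GenomeCDSSet

FRAME_OFFSETS = {"+2": 1, "+3": 2}


@dataclasses.dataclass
class OSCCountRecord:
    per_gene: list[tuple[str, int, int, int]]  # (gene id, n2, n3, codons)
    N2: int
    N3: int
    total_codons: int

    @property
    def density2(self) -> float:
        return 100.0 * self.N2 / self.total_codons

    @property
    def density3(self) -> float:
        return 100.0 * self.N3 / self.total_codons

    @property
    def density_total(self) -> float:
        return self.density2 + self.density3


@dataclasses.dataclass
class OSCUsageVector:
    """Relative stop-codon frequencies within each shifted frame.

    ``freq`` maps (stop codon, frame) -> frequency; each frame with at least
    one OSC forms a simplex summing to 1. Frames with zero OSCs are flagged
    in ``undefined_frames``.
    """
    freq: dict[tuple[str, str], float]
    undefined_frames: frozenset[str]

    def as_array(self, stops: tuple[str, ...]) -> np.ndarray:
        return np.array([self.freq[(s, f)] for f in ("+2", "+3") for s in stops])


@dataclasses.dataclass
class CompositionStats:
    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc_skew: float
    at_skew: float
    gc_ratio: float


def count_oscs(sequence: str, frame_offset: int, stop_codons) -> int:
    """Count OSCs in one shifted frame of a CDS.

    frame_offset 1 scans frame +2 (triplets from 0-based position 1),
    frame_offset 2 scans frame +3; trailing partial triplets are ignored.
    """
    if frame_offset not in (1, 2):
        raise ValueError("frame_offset must be 1 (frame +2) or 2 (frame +3)")
    encoded = enc.encode_seq(sequence)
    return enc.count_frame_stops(encoded, frame_offset, enc.stop_mask64(stop_codons))


def genome_osc_stats(genome: GenomeCDSSet) -> OSCCountRecord:
    """Count OSCs per gene and pool into genome totals and densities.

    Densities are per 100 codons with the genome's total sense-codon count
    as denominator.
    """
    if not genome.cds:
        raise ValueError(f"genome {genome.organism!r} has no CDS")
    t2, t3 = enc.junction_osc_tables(genome.code.stop_codons)
    per_gene = []
    N2 = N3 = total = 0
    for c in genome.cds:
        codons = enc.codons_from_nt(enc.encode_seq(c.sequence))
        n2, n3 = enc.per_gene_osc_counts(codons, t2, t3)
        per_gene.append((c.id, n2, n3, len(codons)))
        N2 += n2
        N3 += n3
        total += len(codons)
    return OSCCountRecord(per_gene=per_gene, N2=N2, N3=N3, total_codons=total)


def osc_usage(genome: GenomeCDSSet, record: OSCCountRecord | None = None) -> OSCUsageVector:
    """Relative usage of each stop codon within frames +2 and +3."""
    stops = sorted(genome.code.stop_codons)
    smask = {s: enc.codon_index(s) for s in stops}
    counts = {(s, f): 0 for s in stops for f in ("+2", "+3")}
    for c in genome.cds:
        encoded = enc.encode_seq(c.sequence)
        for frame, off in FRAME_OFFSETS.items():
            n = (encoded.size - off) // 3
            if n <= 0:
                continue
            w = encoded[off:off + 3 * n].reshape(n, 3).astype(np.int64)
            codes = 16 * w[:, 0] + 4 * w[:, 1] + w[:, 2]
            for s, idx in smask.items():
                counts[(s, frame)] += int((codes == idx).sum())
    freq: dict[tuple[str, str], float] = {}
    undefined = set()
    for frame in ("+2", "+3"):
        tot = sum(counts[(s, frame)] for s in stops)
        if tot == 0:
            undefined.add(frame)
            for s in stops:
                freq[(s, frame)] = math.nan
        else:
            for s in stops:
                freq[(s, frame)] = counts[(s, frame)] / tot
    return OSCUsageVector(freq=freq, undefined_frames=frozenset(undefined))


def composition_stats(genome: GenomeCDSSet) -> CompositionStats:
    """G+C (overall and per codon position), GC/AT skew, [GC]:[AT] ratio.

    Pooled over all CDS nucleotides of the genome.
    """
    nt_counts = np.zeros(4, dtype=np.int64)
    pos_gc = np.zeros(3, dtype=np.int64)
    pos_n = np.zeros(3, dtype=np.int64)
    for c in genome.cds:
        encoded = enc.encode_seq(c.sequence)
        nt_counts += np.bincount(encoded, minlength=4)
        tri = encoded.reshape(-1, 3)
        isgc = (tri == 1) | (tri == 2)  # C or G
        pos_gc += isgc.sum(axis=0)
        pos_n += tri.shape[0]
    a, c_, g, t = (int(x) for x in nt_counts)
    total = a + c_ + g + t
    if total == 0:
        raise ValueError("empty genome")
    gc = (g + c_) / total
    gc123 = pos_gc / np.maximum(pos_n, 1)
    return CompositionStats(
        gc=gc, gc1=float(gc123[0]), gc2=float(gc123[1]), gc3=float(gc123[2]),
        gc_skew=(g - c_) / (g + c_) if g + c_ else math.nan,
        at_skew=(a - t) / (a + t) if a + t else math.nan,
        gc_ratio=(g + c_) / (a + t) if a + t else math.inf,
    )


def frame_bias(record: OSCCountRecord) -> float:
    """log10(N2/N3); NaN (flagged undefined) when a frame has no OSCs."""
    if record.N3 == 0 or record.N2 == 0:
        return math.nan
    return math.log10(record.N2 / record.N3)


def metrics_table(genomes, records=None) -> pd.DataFrame:
    """One row of metrics per genome, suitable for TSV export."""
    rows = []
    for i, g in enumerate(genomes):
        rec = records[i] if records else genome_osc_stats(g)
        comp = composition_stats(g)
        usage = osc_usage(g)
        row = {
            "organism": g.organism, "genus": g.genus, "division": g.division,
            "table_id": g.genetic_code, "n_genes": len(g.cds),
            "total_codons": rec.total_codons,
            "N2": rec.N2, "N3": rec.N3,
            "density2": rec.density2, "density3": rec.density3,
            "density_total": rec.density_total,
            "frame_bias_log10": frame_bias(rec),
            "gc": comp.gc, "gc1": comp.gc1, "gc2": comp.gc2, "gc3": comp.gc3,
            "gc_skew": comp.gc_skew, "at_skew": comp.at_skew,
            "gc_ratio": comp.gc_ratio,
        }
        for (s, f), v in usage.freq.items():
            row[f"usage_{s}_{f}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
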