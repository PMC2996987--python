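"""Reading, filtering and grouping of protein-coding sequences.

CDS records come from GenBank flat files (strand-resolved via the feature
location) or pre-extracted multi-FASTA. Filtering enforces the working
invariants of every downstream model: sequences are pure ACGT, a whole
number of codons, at least `min_codons` long, and free of internal in-frame
stop codons of their genetic code. Terminal stop codons are stripped by
default so that all retained sequences consist of sense codons only.
"""
from __future__ import annotations

import dataclasses
from collections import Counter, defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = frozenset("ACGT")

#: translation tables the pipeline accepts (bacterial/plastid, Mollicutes,
#: vertebrate/yeast/ascidian mitochondrial)
SUPPORTED_TABLES = (11, 4, 2, 3, 13)


@dataclasses.dataclass(frozen=True)
class GeneticCode:
    """An NCBI translation table reduced to what OSC analysis needs."""

    table_id: int
    stop_codons: frozenset[str]

    @classmethod
    def from_table_id(cls, table_id: int) -> "GeneticCode":
        try:
            table = CodonTable.unambiguous_dna_by_id[table_id]
        except KeyError as exc:
            raise ValueError(f"unknown NCBI translation table {table_id}") from exc
        return cls(table_id=table_id, stop_codons=frozenset(table.stop_codons))

    @property
    def sense_codons(self) -> tuple[str, ...]:
        from ._encoding import ALL_CODONS

        return tuple(c for c in ALL_CODONS if c not in self.stop_codons)

    def translate(self, codon: str) -> str:
        table = CodonTable.unambiguous_dna_by_id[self.table_id]
        if codon in self.stop_codons:
            return "*"
        return table.forward_table[codon]


@dataclasses.dataclass
class CodingSequence:
    id: str
    organism: str
    sequence: str
    genetic_code: int
    pseudo: bool = False
    partial: bool = False

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3


@dataclasses.dataclass
class GenomeCDSSet:
    organism: str
    genus: str
    division: str
    genetic_code: int
    cds: list[CodingSequence]
    ogt_category: str | None = None
    ogt_celsius: float | None = None

    @property
    def total_codons(self) -> int:
        return sum(c.n_codons for c in self.cds)

    @property
    def total_nt(self) -> int:
        return sum(len(c.sequence) for c in self.cds)

    @property
    def code(self) -> GeneticCode:
        return GeneticCode.from_table_id(self.genetic_code)


def load_cds(path, format: str, table_id: int) -> list[CodingSequence]:
    """Read CDS records without filtering.

    GenBank CDS features are extracted on the coding strand (minus-strand
    features are reverse-complemented by the location extractor). FASTA
    entries become one record each, ids taken from headers.
    """
    if table_id not in CodonTable.unambiguous_dna_by_id:
        raise ValueError(f"unknown NCBI translation table {table_id}")
    path = Path(path)
    records: list[CodingSequence] = []
    if format == "genbank":
        for rec in SeqIO.parse(str(path), "genbank"):
            organism = rec.annotations.get("organism", rec.id)
            for feat in rec.features:
                if feat.type != "CDS":
                    continue
                quals = feat.qualifiers
                cid = (quals.get("locus_tag") or quals.get("protein_id")
                       or quals.get("gene") or [f"{rec.id}_{feat.location.start}"])[0]
                seq = str(feat.location.extract(rec.seq)).upper()
                loc_str = str(feat.location)
                records.append(CodingSequence(
                    id=cid, organism=organism, sequence=seq, genetic_code=table_id,
                    pseudo="pseudo" in quals or "pseudogene" in quals,
                    partial="<" in loc_str or ">" in loc_str,
                ))
    elif format == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append(CodingSequence(
                id=rec.id, organism=rec.description, sequence=str(rec.seq).upper(),
                genetic_code=table_id))
    else:
        raise ValueError(f"unknown format {format!r}; expected 'genbank' or 'fasta'")
    if not records and path.stat().st_size == 0:
        raise ValueError(f"{path} is empty or not valid {format}")
    return records


def _has_internal_stop(seq: str, stops: frozenset[str]) -> bool:
    return any(seq[i:i + 3] in stops for i in range(0, len(seq) - 3, 3))


def filter_cds(records: Sequence[CodingSequence], min_codons: int = 100,
               keep_terminal_stop: bool = False):
    """Apply inclusion filters; returns (kept, exclusion report Counter).

    The terminal stop codon is stripped unless ``keep_terminal_stop``; the
    length threshold counts the remaining sense codons, which makes the
    filter idempotent. Exclusion reasons: ``annotated-pseudogene``,
    ``ambiguous-base``, ``length-not-multiple-of-3``, ``short``,
    ``internal-stop``.
    """
    kept: list[CodingSequence] = []
    report: Counter[str] = Counter()
    for rec in records:
        seq = rec.sequence.upper()
        if rec.pseudo:
            report["annotated-pseudogene"] += 1
            continue
        if set(seq) - _VALID:
            report["ambiguous-base"] += 1
            continue
        if len(seq) % 3:
            report["length-not-multiple-of-3"] += 1
            continue
        stops = GeneticCode.from_table_id(rec.genetic_code).stop_codons
        if _has_internal_stop(seq, stops):
            report["internal-stop"] += 1
            continue
        if not keep_terminal_stop and seq[-3:] in stops:
            seq = seq[:-3]
        if len(seq) // 3 < min_codons:
            report["short"] += 1
            continue
        kept.append(dataclasses.replace(rec, sequence=seq))
    return kept, report


def select_one_per_genus(genomes: Sequence[GenomeCDSSet], seed: int) -> list[GenomeCDSSet]:
    """Keep one genome per genus, chosen uniformly at random under `seed`.

    Input order is preserved among the selected genomes.
    """
    by_genus: dict[str, list[int]] = defaultdict(list)
    for i, g in enumerate(genomes):
        if not g.genus:
            raise ValueError(f"genome {g.organism!r} has no genus label")
        by_genus[g.genus].append(i)
    rng = np.random.default_rng(seed)
    chosen = set()
    for genus in sorted(by_genus):
        idx = by_genus[genus]
        chosen.add(idx[rng.integers(len(idx))])
    return [g for i, g in enumerate(genomes) if i in chosen]


def build_metagenome(genomes: Sequence[GenomeCDSSet], target_mb: float,
                     seed: int) -> GenomeCDSSet:
    """Concatenate randomly drawn genomes into an artificial metagenome.

    Genomes are drawn without replacement in seed-determined order until the
    pooled CDS size first reaches ``target_mb`` megabases.
    """
    if target_mb <= 0:
        raise ValueError("target_mb must be positive")
    codes = {g.genetic_code for g in genomes}
    if len(codes) > 1:
        raise ValueError(f"mixed genetic codes in metagenome pool: {sorted(codes)}")
    target_nt = target_mb * 1e6
    total = sum(g.total_nt for g in genomes)
    if total < target_nt:
        raise ValueError(
            f"pool holds {total} nt, {target_nt - total:.0f} short of target")
    order = np.random.default_rng(seed).permutation(len(genomes))
    picked: list[GenomeCDSSet] = []
    size = 0
    for i in order:
        picked.append(genomes[i])
        size += genomes[i].total_nt
        if size >= target_nt:
            break
    cds = [c for g in picked for c in g.cds]
    name = "metagenome(" + "+".join(g.organism for g in picked) + ")"
    return GenomeCDSSet(organism=name, genus="metagenome", division="mixed",
                        genetic_code=codes.pop(), cds=cds)


def write_fasta(cds: Iterable[CodingSequence], path) -> None:
    recs = [SeqRecord(Seq(c.sequence), id=c.id, description=c.organism) for c in cds]
    SeqIO.write(recs, str(path), "fasta")


def write_exclusion_report(report: Counter, path) -> None:
    pd.DataFrame(sorted(report.items()), columns=["reason", "count"]).to_csv(
        path, sep="\t", index=False)


MANIFEST_COLUMNS = ["path", "format", "organism", "genus", "division", "table_id",
                    "ogt_category", "ogt_celsius"]


def load_manifest(manifest_path, min_codons: int = 100,
                  keep_terminal_stop: bool = False):
    """Load a genome manifest TSV into filtered GenomeCDSSet objects.

    Returns (genomes, skipped) where skipped maps organism -> reason for
    entries that could not be loaded.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing required columns: {missing}")
    genomes: list[GenomeCDSSet] = []
    skipped: dict[str, str] = {}
    for _, row in df.iterrows():
        organism = row["organism"]
        try:
            path = Path(row["path"])
            if not path.is_absolute():
                path = manifest_path.parent / path
            table_id = int(row["table_id"])
            records = load_cds(path, row["format"], table_id)
            kept, _ = filter_cds(records, min_codons=min_codons,
                                 keep_terminal_stop=keep_terminal_stop)
            ogt_cat = row.get("ogt_category")
            ogt_c = row.get("ogt_celsius")
            genomes.append(GenomeCDSSet(
                organism=organism, genus=row["genus"], division=row["division"],
                genetic_code=table_id, cds=kept,
                ogt_category=None if pd.isna(ogt_cat) else ogt_cat,
                ogt_celsius=None if pd.isna(ogt_c) else float(ogt_c)))
        except (OSError, ValueError) as exc:
            skipped[str(organism)] = str(exc)
    return genomes, skipped
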