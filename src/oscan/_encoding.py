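"""Integer encodings of nucleotides and codons plus vectorised OSC kernels.

Nucleotides map A,C,G,T -> 0,1,2,3; a codon is a base-4 integer in [0, 64).
All heavy counting and sampling in the package runs on these arrays; strings
are materialised only at I/O boundaries.
"""
from __future__ import annotations

import numpy as np

NT = "ACGT"
_NT_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(NT):
    _NT_CODE[ord(_c)] = _i
    _NT_CODE[ord(_c.lower())] = _i

_CODE_NT = np.frombuffer(NT.encode(), dtype=np.uint8)

ALL_CODONS = tuple(a + b + c for a in NT for b in NT for c in NT)


def encode_seq(seq: str) -> np.ndarray:
    """Encode a DNA string to a uint8 array; raises on non-ACGT characters."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    enc = _NT_CODE[raw]
    if enc.max(initial=0) == 255:
        bad = chr(raw[enc == 255][0])
        raise ValueError(f"non-DNA character {bad!r} in sequence")
    return enc


def decode_seq(enc: np.ndarray) -> str:
    return _CODE_NT[enc].tobytes().decode()


def codon_index(codon: str) -> int:
    a, b, c = (NT.index(x) for x in codon.upper())
    return 16 * a + 4 * b + c


def codon_str(idx: int) -> str:
    return ALL_CODONS[idx]


def codons_from_nt(enc: np.ndarray) -> np.ndarray:
    """View a length-3L nt array as L codon indices."""
    if enc.size % 3:
        raise ValueError("nucleotide array length not a multiple of 3")
    tri = enc.reshape(-1, 3).astype(np.int64)
    return 16 * tri[:, 0] + 4 * tri[:, 1] + tri[:, 2]


def nt_from_codons(codons: np.ndarray) -> np.ndarray:
    out = np.empty(3 * len(codons), dtype=np.uint8)
    out[0::3] = codons // 16
    out[1::3] = (codons // 4) % 4
    out[2::3] = codons % 4
    return out


def stop_indices(stop_codons) -> np.ndarray:
    return np.array(sorted(codon_index(s) for s in stop_codons), dtype=np.int64)


def stop_mask64(stop_codons) -> np.ndarray:
    mask = np.zeros(64, dtype=bool)
    mask[stop_indices(stop_codons)] = True
    return mask


def count_frame_stops(enc: np.ndarray, offset: int, smask: np.ndarray) -> int:
    """Count non-overlapping triplets starting at `offset` that are stops.

    `offset` is the 0-based start of the shifted frame (1 for frame +2,
    2 for frame +3); trailing 1-2 nt are ignored.
    """
    n = (enc.size - offset) // 3
    if n <= 0:
        return 0
    w = enc[offset:offset + 3 * n].reshape(n, 3).astype(np.int64)
    codes = 16 * w[:, 0] + 4 * w[:, 1] + w[:, 2]
    return int(smask[codes].sum())


def junction_osc_tables(stop_codons):
    """64x64 boolean tables marking codon pairs whose junction forms an OSC.

    In a gene read as codons c_1..c_L every shifted-frame window spans one
    junction: frame +2 reads (last two nt of c_i) + (first nt of c_{i+1});
    frame +3 reads (last nt of c_i) + (first two nt of c_{i+1}).
    """
    smask = stop_mask64(stop_codons)
    c = np.arange(64)
    # suffix/prefix nucleotide digits of each codon
    n1, n2, n3 = c // 16, (c // 4) % 4, c % 4
    # frame +2: n2(c1), n3(c1), n1(c2)
    t2 = smask[(16 * n2[:, None] + 4 * n3[:, None]) + n1[None, :]]
    # frame +3: n3(c1), n1(c2), n2(c2)
    t3 = smask[16 * n3[:, None] + (4 * n1 + n2)[None, :]]
    return t2, t3


def count_oscs_codon_genes(codons: np.ndarray, lengths: np.ndarray, t2, t3):
    """Per-frame OSC counts over concatenated codon-index genes.

    `lengths` gives codon counts per gene; junctions never span gene ends.
    Returns (N2, N3) totals.
    """
    if codons.size == 0:
        return 0, 0
    a, b = codons[:-1], codons[1:]
    valid = np.ones(codons.size - 1, dtype=bool)
    ends = np.cumsum(lengths)[:-1] - 1  # last codon of each gene but the final one
    valid[ends] = False
    return int(t2[a, b][valid].sum()), int(t3[a, b][valid].sum())


def per_gene_osc_counts(codons: np.ndarray, t2, t3):
    """(n2, n3) for a single gene given as codon indices."""
    if codons.size < 2:
        return 0, 0
    a, b = codons[:-1], codons[1:]
    return int(t2[a, b].sum()), int(t3[a, b].sum())
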