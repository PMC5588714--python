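"""TE edge-sequence database: the junction probe set.

From each library TE the terminal 100 bp of each end is taken as an "edge";
a junction read spans the TE extremity (the outward-facing end of an edge)
into unique genomic flank. Identical edge sequences across family members
are collapsed, retaining every source TE, so junction hits are never double
counted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO

logger = logging.getLogger(__name__)

EDGE_LEN = 100
FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"

CLASS_DNA = "DNA"
CLASS_GYPSY = "LTR/Gypsy"
CLASS_COPIA = "LTR/Copia"
CLASS_OTHER = "other"


def classify_te(header: str) -> str:
    """Superfamily class from a TE identifier / FASTA header token.

    Follows the maize three-letter code convention (first letter D = DNA
    transposon, RLG = Gypsy, RLC = Copia) with free-text fallbacks; anything
    unrecognized is "other".
    """
    token = header.split()[0].strip(">") if header.strip() else ""
    low = token.lower()
    if low.startswith("rlg") or "gypsy" in low:
        return CLASS_GYPSY
    if low.startswith("rlc") or "copia" in low:
        return CLASS_COPIA
    if token[:1].upper() == "D" or "dna" in low.split("_"):
        return CLASS_DNA
    if token and not token[:1].upper() in ("D", "R"):
        logger.warning("unrecognized TE class token %r; assigning 'other'", token)
    return CLASS_OTHER


def te_family(te_id: str) -> str:
    """Family name: the leading code token of the identifier."""
    return te_id.split("_")[0] if "_" in te_id else te_id


@dataclass
class TEEdge:
    edge_id: str
    te_ids: list  # all source TEs whose edge collapsed onto this sequence
    end: str  # five_prime | three_prime
    sequence: bytes
    te_class: str
    families: list = field(default_factory=list)


@dataclass
class EdgeDB:
    edges: list  # of TEEdge
    te_classes: dict  # te_id -> class

    def __len__(self):
        return len(self.edges)


def build_edge_db(te_library: dict, te_classes: dict | None = None) -> EdgeDB:
    """Two edges per TE (terminal <=100 bp each); duplicates collapsed.

    ``te_library`` maps te_id -> sequence (bytes or str). TEs shorter than
    2x the edge length yield overlapping edges; TEs shorter than the edge
    length contribute their whole sequence at both ends.
    """
    if not te_library:
        raise ValueError("empty TE library")
    if te_classes is None:
        te_classes = {tid: classify_te(tid) for tid in te_library}
    merged: dict[tuple, TEEdge] = {}
    for te_id, seq in te_library.items():
        s = seq.encode() if isinstance(seq, str) else bytes(seq)
        if len(s) < 2:
            raise ValueError(f"TE {te_id} shorter than 2 bp")
        for end, edge_seq in ((FIVE_PRIME, s[:EDGE_LEN]), (THREE_PRIME, s[-EDGE_LEN:])):
            key = (end, edge_seq)
            if key in merged:
                merged[key].te_ids.append(te_id)
                merged[key].families.append(te_family(te_id))
                if merged[key].te_class != te_classes[te_id]:
                    warnings.warn(
                        f"edge shared across classes ({merged[key].te_class} vs "
                        f"{te_classes[te_id]}); keeping first")
            else:
                merged[key] = TEEdge(
                    edge_id=f"{te_id}:{'5p' if end == FIVE_PRIME else '3p'}",
                    te_ids=[te_id], end=end, sequence=edge_seq,
                    te_class=te_classes[te_id], families=[te_family(te_id)])
    return EdgeDB(edges=list(merged.values()), te_classes=dict(te_classes))


def load_te_library(fasta_path) -> tuple[dict, dict]:
    """Read a TE library FASTA; returns (id -> sequence bytes, id -> class)."""
    lib, classes = {}, {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        lib[rec.id] = str(rec.seq).upper().encode()
        classes[rec.id] = classify_te(rec.description or rec.id)
    if not lib:
        raise ValueError(f"no sequences in {fasta_path}")
    return lib, classes


def write_edge_db(db: EdgeDB, fasta_path, tsv_path) -> None:
    """Persist edges as FASTA plus a TSV sidecar (edge_id, te_ids, end, class)."""
    with open(fasta_path, "w") as fa, open(tsv_path, "w") as tsv:
        tsv.write("edge_id\tte_ids\tend\tclass\n")
        for e in db.edges:
            fa.write(f">{e.edge_id}\n{e.sequence.decode()}\n")
            tsv.write(f"{e.edge_id}\t{','.join(e.te_ids)}\t{e.end}\t{e.te_class}\n")
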