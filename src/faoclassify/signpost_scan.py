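"""Genomic screen for the two dehydrogenase signposts.

Bacterial FAO dehydrogenases are flagged by (I) a twin-arginine (TAT)
export signal on the FAO itself and (II) a cytochrome c gene encoded next
to it (or fused to it).  Scanning an annotated contig around each FAO gene
assigns one of four operon categories:

* ``black`` — no signal peptide, no adjacent CytC (putative oxidase)
* ``blue``  — TAT signal and an adjacent CytC gene (putative dehydrogenase)
* ``green`` — TAT signal with the CytC fused into the same polypeptide
* ``red``   — TAT signal but no adjacent CytC (periplasmic, oxidant unclear)

Signal peptides are detected with transparent motif heuristics (the TAT
S/T-R-R-x-Phi consensus; the Sec charged-n-region / hydrophobic-core /
A-x-A cleavage architecture) rather than a trained predictor, which keeps
the rules auditable and testable; callers working on real proteomes can
substitute an external predictor through the same SignalCall interface.
C-type cytochromes are recognized by their covalent heme-attachment motif
CXXCH: one motif in a small (~11 kDa) protein is a class I monoheme CytC,
two motifs in a ~20 kDa protein a c4-type diheme.

The module also provides global pairwise identity and the >98%-identity
deduplication used to build nonredundant sequence sets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import Align

__all__ = [
    "GeneRecord",
    "SignalCall",
    "CytcEvidence",
    "OperonCategory",
    "CATEGORIES",
    "detect_tat_signal",
    "detect_sec_signal",
    "detect_cytc",
    "detect_fusion",
    "scan_fao_context",
    "scan_genbank",
    "read_genbank",
    "pairwise_identity",
    "dedupe_by_identity",
]

CATEGORIES = ("black", "blue", "green", "red")

_AA = set("ACDEFGHIKLMNPQRSTVWY")
HYDROPHOBIC = "AFGILMVW"

_TAT_MOTIF = re.compile(r"[ST]RR.[AFGILMVW]")
_CXXCH = re.compile(r"C..CH")


@dataclass(frozen=True)
class GeneRecord:
    """One annotated CDS. Coordinates are 1-based inclusive (GenBank style)."""

    locus_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    product: str
    protein: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.locus_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_id}: strand must be '+' or '-'")
        if not self.protein:
            raise ValueError(f"{self.locus_id}: CDS requires a protein sequence")


@dataclass(frozen=True)
class SignalCall:
    type: str  # "TAT" | "Sec" | "none"
    motif_position: int | None = None  # 1-based
    cleavage_position: int | None = None
    evidence: str = ""


@dataclass(frozen=True)
class CytcEvidence:
    motif_count: int
    motif_positions: tuple[int, ...]  # 1-based starts
    length: int
    cytc_class: str  # "class_I_monoheme" | "c4_diheme" | "not_cytc"


@dataclass(frozen=True)
class OperonCategory:
    category: str
    fao: GeneRecord
    supporting: tuple[GeneRecord, ...] = ()
    evidence: str = ""


def _check_protein(protein: str, min_len: int) -> str:
    protein = protein.upper().rstrip("*")
    if len(protein) < min_len:
        raise ValueError(f"protein shorter than {min_len} residues")
    bad = set(protein) - _AA
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)}")
    return protein


def detect_tat_signal(protein: str) -> SignalCall:
    """Twin-arginine signal: [S/T]-R-R-x-Phi within the first 35 residues,
    followed within 25 residues by a run of >= 6 hydrophobics (the h-region).
    """
    protein = _check_protein(protein, 30)
    for m in _TAT_MOTIF.finditer(protein[:40]):
        if m.start() >= 35:
            break
        window = protein[m.end():m.end() + 31]
        run = re.search(f"[{HYDROPHOBIC}]{{6,}}", window)
        if run is not None and run.start() <= 25:
            return SignalCall(
                "TAT",
                motif_position=m.start() + 1,
                evidence=(f"twin-arginine motif {m.group(0)} at {m.start() + 1}; "
                          f"hydrophobic h-region at offset {run.start() + 1}"),
            )
    return SignalCall("none", evidence="no twin-arginine consensus")


def detect_sec_signal(protein: str) -> SignalCall:
    """Sec signal: a basic residue in the n-region (positions 1-7), a run of
    >= 7 hydrophobics within positions 5-25, and an A-x-A cleavage motif
    within positions 15-35.  Mutually exclusive with a TAT call.
    """
    protein = _check_protein(protein, 30)
    if detect_tat_signal(protein).type == "TAT":
        return SignalCall("none", evidence="TAT signal takes precedence")
    if not any(c in "KR" for c in protein[:7]):
        return SignalCall("none", evidence="no K/R in the n-region")
    core = re.search(f"[{HYDROPHOBIC}]{{7,}}", protein[4:25])
    if core is None:
        return SignalCall("none", evidence="no hydrophobic core in positions 5-25")
    cleav = None
    for i in range(14, min(33, len(protein) - 2)):
        if protein[i] == "A" and protein[i + 2] == "A":
            cleav = i  # 0-based index of the first A
            break
    if cleav is None:
        return SignalCall("none", evidence="no A-x-A cleavage motif in 15-35")
    return SignalCall(
        "Sec",
        motif_position=core.start() + 5,
        cleavage_position=cleav + 3,  # cleavage after the second A (1-based)
        evidence=(f"basic n-region; hydrophobic core at {core.start() + 5}; "
                  f"AxA cleavage ending at {cleav + 3}"),
    )


def detect_cytc(protein: str) -> CytcEvidence:
    """Scan for covalent heme-attachment motifs (CXXCH, non-overlapping).

    One motif in a mature chain of <= 130 aa is a class I monoheme CytC
    (~11 kDa); two motifs in a 150-250 aa chain a c4-type diheme (~20 kDa).
    Counts outside those windows are not called cytochromes.
    """
    protein = _check_protein(protein, 50)
    matches = list(_CXXCH.finditer(protein))
    positions = tuple(m.start() + 1 for m in matches)
    count = len(matches)
    mature_len = len(protein)
    sec = detect_sec_signal(protein)
    if sec.type == "Sec" and sec.cleavage_position is not None:
        mature_len = len(protein) - sec.cleavage_position
    if count == 1 and mature_len <= 130:
        cls = "class_I_monoheme"
    elif count == 2 and 150 <= len(protein) <= 250:
        cls = "c4_diheme"
    else:
        cls = "not_cytc"
    return CytcEvidence(count, positions, len(protein), cls)


def detect_fusion(protein: str, fao_length_floor: int = 450) -> bool:
    """FAO-CytC fusion: a TAT-exported polypeptide long enough to contain an
    FAO domain with a heme-attachment motif in its C-terminal 150 residues.
    """
    protein = protein.upper().rstrip("*")
    if len(protein) < fao_length_floor:
        return False
    if detect_tat_signal(protein).type != "TAT":
        return False
    return _CXXCH.search(protein[-150:]) is not None


def scan_fao_context(
    records: list[GeneRecord],
    fao_index: int,
    window_bp: int = 3000,
    window_genes: int = 2,
) -> OperonCategory:
    """Assign the operon category of the FAO at ``records[fao_index]``.

    ``records`` must be the ordered genes of one contig.  A CytC gene counts
    as adjacent when at most ``window_genes`` genes intervene and the gap
    between gene boundaries is at most ``window_bp``.  Strand-agnostic.
    """
    if not records:
        raise ValueError("empty contig")
    if not (0 <= fao_index < len(records)):
        raise ValueError(f"fao_index {fao_index} out of range")
    fao = records[fao_index]

    if detect_fusion(fao.protein):
        return OperonCategory("green", fao,
                              evidence="TAT FAO with C-terminal CXXCH (fusion)")

    has_tat = detect_tat_signal(fao.protein).type == "TAT"
    neighbors: list[GeneRecord] = []
    for j, rec in enumerate(records):
        if j == fao_index or rec.contig_id != fao.contig_id:
            continue
        if abs(j - fao_index) > window_genes + 1:
            continue
        gap = max(rec.start - fao.end, fao.start - rec.end, 0)
        if gap > window_bp:
            continue
        neighbors.append(rec)

    cytc_hits = tuple(
        rec for rec in neighbors
        if len(rec.protein) >= 50 and detect_cytc(rec.protein).cytc_class != "not_cytc"
    )
    if has_tat and cytc_hits:
        return OperonCategory(
            "blue", fao, supporting=cytc_hits,
            evidence=f"TAT FAO with adjacent CytC: "
                     f"{', '.join(r.locus_id for r in cytc_hits)}",
        )
    if has_tat:
        return OperonCategory("red", fao,
                              evidence="TAT FAO, no CytC within the window")
    return OperonCategory("black", fao, evidence="no signal peptide, no CytC")


def read_genbank(path) -> dict[str, list[GeneRecord]]:
    """Read CDS features (with /translation) from a GenBank flat file,
    grouped per contig and ordered by start coordinate."""
    from Bio import SeqIO

    contigs: dict[str, list[GeneRecord]] = {}
    for rec in SeqIO.parse(str(path), "genbank"):
        genes = []
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            translation = quals.get("translation", [""])[0]
            if not translation:
                continue
            genes.append(GeneRecord(
                locus_id=quals.get("locus_tag", [f"{rec.id}_{len(genes)}"])[0],
                contig_id=rec.id,
                start=int(feat.location.start) + 1,
                end=int(feat.location.end),
                strand="+" if feat.location.strand != -1 else "-",
                product=quals.get("product", [""])[0],
                protein=translation,
            ))
        genes.sort(key=lambda g: g.start)
        contigs[rec.id] = genes
    return contigs


_FAO_PRODUCT = re.compile(r"amine oxid|oxidoreductase|flavin", re.IGNORECASE)


def scan_genbank(path, fao_product_pattern: str | re.Pattern | None = None,
                 window_bp: int = 3000, window_genes: int = 2):
    """Scan a GenBank file and categorize every FAO gene found.

    FAO genes are identified by their product annotation (default pattern
    matches amine oxidase / oxidoreductase / flavin annotations).  Returns a
    pandas DataFrame with locus, contig, category and evidence columns.
    """
    import pandas as pd

    pattern = (re.compile(fao_product_pattern, re.IGNORECASE)
               if isinstance(fao_product_pattern, str)
               else fao_product_pattern or _FAO_PRODUCT)
    rows = []
    for contig_id, genes in read_genbank(path).items():
        for i, gene in enumerate(genes):
            if not pattern.search(gene.product):
                continue
            cat = scan_fao_context(genes, i, window_bp=window_bp,
                                   window_genes=window_genes)
            rows.append({
                "locus": gene.locus_id,
                "contig": contig_id,
                "category": cat.category,
                "evidence": cat.evidence,
                "supporting": ";".join(r.locus_id for r in cat.supporting),
            })
    return pd.DataFrame(rows, columns=["locus", "contig", "category",
                                       "evidence", "supporting"])


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(a: str, b: str) -> float:
    """Global alignment identity: matches / aligned columns, counting
    internal gap columns in the denominator but excluding terminal gaps."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a, b = a.upper().rstrip("*"), b.upper().rstrip("*")
    if a == b:
        return 1.0
    alignment = _aligner().align(a, b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    # trim terminal-gap columns (overhangs of either sequence)
    start = max(len(row_a) - len(row_a.lstrip("-")),
                len(row_b) - len(row_b.lstrip("-")))
    stop = len(row_a) - max(len(row_a) - len(row_a.rstrip("-")),
                            len(row_b) - len(row_b.rstrip("-")))
    if stop <= start:
        return 0.0
    cols = range(start, stop)
    matches = sum(1 for i in cols if row_a[i] == row_b[i] and row_a[i] != "-")
    return matches / (stop - start)


def dedupe_by_identity(
    seqs: list[str], cutoff: float = 0.98
) -> tuple[list[int], dict[int, int]]:
    """Greedy single-linkage deduplication in input order.

    A sequence is dropped when its identity to an already-kept sequence
    exceeds ``cutoff``.  Returns the kept indices and a map from every index
    to the kept representative it clusters with.  Deterministic for a fixed
    input order; idempotent.
    """
    for i, s in enumerate(seqs):
        if not s:
            raise ValueError(f"sequence {i} is empty")
    kept: list[int] = []
    cluster: dict[int, int] = {}
    for i, s in enumerate(seqs):
        rep = None
        for j in kept:
            if pairwise_identity(s, seqs[j]) > cutoff:
                rep = j
                break
        if rep is None:
            kept.append(i)
            cluster[i] = i
        else:
            cluster[i] = rep
    return kept, cluster
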