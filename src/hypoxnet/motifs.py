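"""IUPAC consensus motif scanning and N-degron detection.

Scans promoter windows for the hypoxia-responsive promoter element
(HRPE, consensus ``GCCVCYGGTTTY``), translates coding sequences, and
detects the N-terminal cys/arg N-degron signature ``MCGGAI/V`` that marks
ERF VII transcription factors for oxygen-dependent degradation.

Matching is exact consensus matching: a window matches when every position
is contained in the IUPAC class of the corresponding pattern letter. An
``N`` in the *input* sequence only matches an ``N`` pattern position.
Coordinates are 0-based half-open on the forward strand; reverse-strand
hits are reported at their forward-strand start.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

HRPE = "GCCVCYGGTTTY"
N_DEGRON_PREFIXES = ("MCGGAI", "MCGGAV")

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


@dataclass(frozen=True)
class MotifHit:
    """One consensus-motif match.

    ``offset`` is the 0-based start on the forward strand of the scanned
    sequence; ``matched`` is the L-mer read 5'->3' on the hit strand.
    """

    seq_id: str
    offset: int
    strand: str
    matched: str


def expand_iupac(code: str) -> frozenset[str]:
    """Return the set of unambiguous bases an IUPAC letter stands for."""
    try:
        return IUPAC_CODES[code.upper()]
    except KeyError:
        raise ValueError(f"invalid IUPAC code: {code!r}") from None


def _pattern_regex(pattern: str) -> re.Pattern:
    parts = []
    for letter in pattern.upper():
        bases = expand_iupac(letter)
        # sequence N matches only where the pattern itself allows anything
        cls = "".join(sorted(bases)) + ("N" if letter == "N" else "")
        parts.append(f"[{cls}]")
    # lookahead so overlapping occurrences are all reported
    return re.compile("(?=(" + "".join(parts) + "))")


def scan_motif(
    sequence: str,
    motif: str = HRPE,
    *,
    both_strands: bool = True,
    seq_id: str = "",
) -> list[MotifHit]:
    """All occurrences of an IUPAC consensus in ``sequence``.

    Soft-masked (lowercase) input is uppercased first. With
    ``both_strands`` the reverse complement is scanned too and hits are
    mapped back to forward coordinates with strand ``-``. A sequence
    shorter than the motif yields no hits.
    """
    seq = sequence.upper()
    L = len(motif)
    if len(seq) < L:
        return []
    rx = _pattern_regex(motif)
    hits = [
        MotifHit(seq_id, m.start(), "+", m.group(1)) for m in rx.finditer(seq)
    ]
    if both_strands:
        rc = str(Seq(seq).reverse_complement())
        for m in rx.finditer(rc):
            fwd_start = len(seq) - m.start() - L
            hits.append(MotifHit(seq_id, fwd_start, "-", m.group(1)))
    return sorted(hits, key=lambda h: (h.offset, h.strand))


def scan_fasta(
    sequences: Mapping[str, str],
    motif: str = HRPE,
    *,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Scan every sequence of a ``{seq_id: sequence}`` mapping."""
    out: list[MotifHit] = []
    for seq_id, seq in sequences.items():
        out.extend(scan_motif(seq, motif, both_strands=both_strands, seq_id=seq_id))
    return out


def hits_to_table(hits: Iterable[MotifHit], motif_len: int | None = None) -> pd.DataFrame:
    """BED-like table of hits (0-based half-open start/end)."""
    rows = [
        {
            "seq_id": h.seq_id,
            "start": h.offset,
            "end": h.offset + len(h.matched),
            "strand": h.strand,
            "matched": h.matched,
        }
        for h in hits
    ]
    return pd.DataFrame(rows, columns=["seq_id", "start", "end", "strand", "matched"])


def presence_table(sequences: Mapping[str, str], motif: str = HRPE) -> pd.DataFrame:
    """Per-sequence presence/absence summary for a consensus motif."""
    hits = scan_fasta(sequences, motif)
    counts = pd.Series(0, index=list(sequences), dtype=int)
    for h in hits:
        counts[h.seq_id] += 1
    return pd.DataFrame(
        {"seq_id": counts.index, "n_hits": counts.values, "present": counts.values > 0}
    )


def translate_cds(cds: str) -> str:
    """Codon-by-codon translation with the standard genetic code.

    Stops at (and excludes) the first stop codon; a trailing partial codon
    is ignored; a codon containing ``N`` translates to ``X``. Characters
    outside ACGTN are rejected.
    """
    seq = cds.upper()
    if len(seq) < 3:
        raise ValueError("coding sequence shorter than one codon")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters in CDS: {sorted(bad)}")
    residues = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            residues.append("X")
            continue
        if codon in _STANDARD_TABLE.stop_codons:
            break
        residues.append(_STANDARD_TABLE.forward_table[codon])
    return "".join(residues)


def has_n_degron(protein: str) -> bool:
    """True iff the first six residues are MCGGAI or MCGGAV."""
    if not protein:
        raise ValueError("empty protein sequence")
    return protein[:6] in N_DEGRON_PREFIXES


def degron_census(cds_sequences: Mapping[str, str]) -> list[str]:
    """IDs whose translated CDS starts with the N-degron signature."""
    return sorted(
        gid for gid, cds in cds_sequences.items() if has_n_degron(translate_cds(cds))
    )


def extract_upstream(
    genome: Mapping[str, str],
    genes: pd.DataFrame,
    n: int = 1000,
) -> dict[str, str]:
    """Strand-aware n-bp windows immediately 5' of each translational start.

    ``genes`` needs columns ``gene_id, seqid, start, end, strand`` with
    1-based inclusive coordinates (GFF3 convention). Windows running off
    the contig edge are truncated with a warning. For minus-strand genes
    the window 3' of ``end`` is reverse complemented.
    """
    out: dict[str, str] = {}
    for row in genes.itertuples(index=False):
        if row.seqid not in genome:
            raise KeyError(f"gene {row.gene_id}: contig {row.seqid!r} not in genome")
        contig = genome[row.seqid]
        if row.strand == "+":
            stop = row.start - 1  # 0-based index of the translational start
            begin = max(0, stop - n)
            window = contig[begin:stop]
        else:
            begin = row.end  # 0-based position just 3' of the gene span
            stop = min(len(contig), begin + n)
            window = str(Seq(contig[begin:stop]).reverse_complement())
        if len(window) < n:
            warnings.warn(
                f"gene {row.gene_id}: upstream window truncated to {len(window)} bp "
                f"at contig edge",
                stacklevel=2,
            )
        out[row.gene_id] = window
    return out
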