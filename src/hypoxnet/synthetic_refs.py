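"""SYNTHETIC stand-ins for the published apple PCO / ERF VII sequences.

The real GDDH13 supplementary sequence files (coding sequences of the
five ERF VII transcription factors; 1000-bp upstream windows of the ten
PCO homologs) are distributed with the study and are not bundled here.
These generators produce synthetic sequences under the published gene
IDs that reproduce the *reported motif structure* — nothing else about
them is biological:

* all five ERF VII coding sequences translate to an N-terminal
  MCGGAI/V degron;
* each of the five B-type (hypoxia-inducible) PCO upstream windows
  carries at least one HRPE instance;
* none of the five A-type (constitutive) PCO upstream windows contains
  an HRPE on either strand.

They exist so the motif-annotation workflow (translate -> degron census;
IUPAC scan -> promoter census) can be exercised end-to-end offline.
"""

from __future__ import annotations

import numpy as np

from .motifs import HRPE, scan_motif
from .simulate import _degron_start, _random_codon, _random_seq, _realize_iupac

ERFVII_IDS: dict[str, str] = {
    "MD09G1174400": "RAP2.12/RAP2.2-like",
    "MD17G1152400": "RAP2.12/RAP2.2-like",
    "MD13G1163300": "RAP2.3-like",
    "MD16G1162900": "RAP2.3-like",
    "MD11G1306500": "HRE2-like",
}

PCO_A_TYPE: tuple[str, ...] = (
    "MD06G1208200",
    "MD14G1218600",
    "MD09G1236500",
    "MD15G1373300",
    "MD17G1266100",
)

PCO_B_TYPE: tuple[str, ...] = (
    "MD14G1006600",
    "MD12G1009100",
    "MD09G1048100",
    "MD12G1009200",
    "MD17G1048300",
)


def synthetic_erfvii_cds(seed: int = 0, n_codons: int = 80) -> dict[str, str]:
    """Synthetic ERF VII coding sequences, each starting MCGGAI/V."""
    rng = np.random.default_rng(seed)
    out = {}
    for gid in ERFVII_IDS:
        body = _degron_start(rng)
        body += "".join(_random_codon(rng) for _ in range(n_codons - 7))
        out[gid] = body + "TAA"
    return out


def synthetic_pco_upstream(seed: int = 0, length: int = 1000) -> dict[str, str]:
    """Synthetic 1000-bp PCO upstream windows with the reported HRPE layout."""
    rng = np.random.default_rng(seed)
    out = {}
    for gid in PCO_B_TYPE:
        seq = _random_seq(rng, length)
        off = int(rng.integers(0, length - len(HRPE) + 1))
        out[gid] = seq[:off] + _realize_iupac(rng, HRPE) + seq[off + len(HRPE):]
    for gid in PCO_A_TYPE:
        while True:
            seq = _random_seq(rng, length)
            if not scan_motif(seq, HRPE):
                break
        out[gid] = seq
    return out
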