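"""The fusion-amplicon grammar.

A three-primer emulsion fusion PCR produces concatemer amplicons

    5'-[F1][target segment | random barcode][bridge][16S V4 segment]-[rc(R2)]-3'

where F1 primes the functional-gene (or synthetic barcode) side, R2 primes
the 16S side from the reverse strand, and the limiting bridge primer
(R1-F2', carrying 16S homology) joins the two amplicons. A read is a valid
fusion only if all three elements are present in this order; the 16S
segment is then trimmed to a fixed length downstream of a conserved V4
anchor site so that phylotype sequences are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import yaml

from epicpcr.iupac import validate_iupac

# Default construct used by the read simulator and the packaged pipeline
# configuration. F1/bridge are synthetic designs; R2 is a concrete
# expansion of the universal 16S 806R primer, and the V4 anchor is the
# conserved 515F-region motif that marks the start of the trimmed segment.
DEFAULT_F1 = "GGCATGGTCAAGATCGTCAA"
DEFAULT_BRIDGE = "CTACGGGAGGCAGCAGTGGGGAATC"
DEFAULT_R2 = "GGACTACCAGGGTATCTAAT"
DEFAULT_ANCHOR = "GTGCCAGCMGCCGCGGTAA"


@dataclass(frozen=True)
class FusionConstructSpec:
    """Primer/bridge layout of a fusion construct.

    Parameters
    ----------
    f1, bridge, r2:
        Forward primer, bridge (junction) sequence and reverse 16S primer,
        5'->3' as synthesized. In a merged read the bridge appears verbatim
        and the read ends with the reverse complement of ``r2``.
    barcode_len:
        Length of the random barcode in the barcode-16S assay (nt).
    anchor_motif:
        Conserved 16S V4 site; the phylotype segment is the ``trim_len``
        bases immediately following it.
    trim_len:
        Length of the retained 16S V4 segment (bp).
    read_len:
        Sequencer read length (bp) for paired-end simulation.
    """

    f1: str = DEFAULT_F1
    bridge: str = DEFAULT_BRIDGE
    r2: str = DEFAULT_R2
    barcode_len: int = 20
    anchor_motif: str = DEFAULT_ANCHOR
    trim_len: int = 121
    read_len: int = 250

    def __post_init__(self) -> None:
        for name in ("f1", "bridge", "r2", "anchor_motif"):
            object.__setattr__(self, name, validate_iupac(getattr(self, name), name))
        if self.barcode_len < 1:
            raise ValueError("barcode_len must be >= 1")
        if self.trim_len < 1:
            raise ValueError("trim_len must be >= 1")
        if self.read_len < len(self.f1) + len(self.bridge):
            raise ValueError("read_len shorter than the constant construct elements")

    @classmethod
    def from_yaml(cls, path: str) -> "FusionConstructSpec":
        with open(path) as fh:
            data: dict[str, Any] = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return {
            "f1": self.f1,
            "bridge": self.bridge,
            "r2": self.r2,
            "barcode_len": self.barcode_len,
            "anchor_motif": self.anchor_motif,
            "trim_len": self.trim_len,
            "read_len": self.read_len,
        }


DEFAULT_CONSTRUCT = FusionConstructSpec()
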