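"""Shared immunophenotype and phenotype vocabulary."""

from __future__ import annotations

from enum import Enum


class Immunophenotype(str, Enum):
    """Two-channel immunostaining signature of an envelope structure.

    The three invagination types distinguished in bovine preimplantation
    nuclei: positive for both the nucleoporin marker and lamin B, lamin B
    only, or nucleoporin only.
    """

    NUP_POS_LAM_POS = "NUP+/LamB+"
    NUP_NEG_LAM_POS = "NUP-/LamB+"
    NUP_POS_LAM_NEG = "NUP+/LamB-"
    NUP_NEG_LAM_NEG = "NUP-/LamB-"

    @classmethod
    def from_flags(cls, lamin_pos: bool, nup_pos: bool) -> "Immunophenotype":
        return {
            (True, True): cls.NUP_POS_LAM_POS,
            (True, False): cls.NUP_NEG_LAM_POS,
            (False, True): cls.NUP_POS_LAM_NEG,
            (False, False): cls.NUP_NEG_LAM_NEG,
        }[(bool(lamin_pos), bool(nup_pos))]


class NucleusPhenotype(str, Enum):
    """Nuclear architecture before vs after major genome activation.

    ``PRE_MGA``: peripheral chromatin with a DNA-free interior lacuna,
    nuclear pores confined to envelope regions contacted by chromatin.
    ``POST_MGA``: a thin chromatin rim along the whole envelope and a
    uniform pore distribution.
    """

    PRE_MGA = "pre_mga"
    POST_MGA = "post_mga"
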