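"""The two-step-PCR amplicon construct.

The first PCR tags each template molecule with a random 13-base UMI on both
ends; the second PCR appends sequencing adapters.  On the forward strand a
finished molecule reads::

    [2nd-PCR fwd primer incl. 3-base anchor] [N13 UMI] [fwd D-loop primer site]
        [D-loop] [revcomp of rev D-loop primer site] [revcomp N13 UMI]
        [revcomp of 2nd-PCR rev primer]

The D-loop primer sites sit in the conserved tRNA-Thr and 12S rRNA regions
flanking the control region and carry degenerate bases where the fish
alignment is not conserved.
"""

from .core_io import revcomp

#: 13-base unique molecular identifier on each end.
UMI_LENGTH = 13

#: Forward universal D-loop primer site (tRNA-Thr side), 2 degenerate codes.
FWD_PRIMER_SITE = "ARAGCRYCGGTCTTGTAA"

#: Reverse universal D-loop primer site (12S rRNA side), 2 degenerate codes.
REV_PRIMER_SITE = "CGGAKACTTGCATGTRTAA"

#: Second-PCR forward primer; its last 3 bases (GTC) are the anchor that
#: separates adapter from UMI.
FWD_2ND_PRIMER = "TACACGACGCTCTTCCGATCTGTC"

#: Second-PCR reverse primer, anchor CAG.
REV_2ND_PRIMER = "AGACGTGTGCTCTTCCGATCTCAG"


def fwd_construct() -> str:
    """Degenerate model of the left flank: adapter+anchor, N13 UMI, primer site."""
    return FWD_2ND_PRIMER + "N" * UMI_LENGTH + FWD_PRIMER_SITE


def rev_construct() -> str:
    """Degenerate model of the right flank, in reverse-primer orientation."""
    return REV_2ND_PRIMER + "N" * UMI_LENGTH + REV_PRIMER_SITE


def assemble_molecule(
    fwd_umi: str, rev_umi: str, fwd_site: str, rev_site: str, dloop: str
) -> str:
    """Forward-strand sequence of a finished second-PCR product.

    ``fwd_site``/``rev_site`` are concrete (non-degenerate) expansions of the
    primer sites, as carried by the primer oligo that tagged the molecule.
    """
    return (
        FWD_2ND_PRIMER
        + fwd_umi
        + fwd_site
        + dloop
        + revcomp(rev_site)
        + revcomp(rev_umi)
        + revcomp(REV_2ND_PRIMER)
    )


def max_umi_pairs_per_molecule(first_pcr_cycles: int) -> int:
    """Upper bound on distinct UMI pairs one template can acquire.

    Two cycles are needed to fix a UMI pair on both strands; every further
    first-PCR cycle can double the number of apparent molecules, so with
    ``c`` cycles one template yields at most ``2**(c-2)`` distinct pairs.
    """
    if first_pcr_cycles < 2:
        raise ValueError("first PCR needs at least 2 cycles to tag both ends")
    return 2 ** (first_pcr_cycles - 2)
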