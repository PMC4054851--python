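"""Bisulfite-clone methylation patterns and their concordance with array calls.

Bisulfite sequencing of cloned PCR products yields a clones x CpGs boolean
matrix for one gene in one sample. Because NotI digestion is blocked only by
methylation of the CpGs inside its recognition site, the site-level
"methylated" verdict requires every NotI-site CpG to be methylated in more
than a threshold fraction of clones. Cross-tabulating that verdict with the
array call separates methylation from deletion: a decreased-signal (MD)
array call without bisulfite methylation points to a deletion.
"""

from __future__ import annotations

import numpy as np

from .model import BisulfiteCloneSet, CallState, ValidationError

__all__ = [
    "classify_concordance",
    "noti_site_methylated",
    "per_cpg_fraction",
]

VERDICTS = (
    "concordant_methylation",
    "discordant_deletion_likely",
    "concordant_retention",
    "discordant_other",
)


def per_cpg_fraction(cs: BisulfiteCloneSet) -> np.ndarray:
    """Fraction of clones methylated at each CpG position."""
    if cs.n_clones == 0:
        raise ValidationError("clone set is empty")
    return cs.matrix.mean(axis=0)


def noti_site_methylated(
    cs: BisulfiteCloneSet, clone_fraction_threshold: float = 0.5
) -> bool:
    """Site-level methylation verdict from the clone matrix.

    True iff *every* CpG of the NotI recognition site is methylated in
    strictly more than ``clone_fraction_threshold`` of clones (exactly at
    threshold counts as unmethylated).
    """
    if not 0 <= clone_fraction_threshold <= 1:
        raise ValidationError("clone_fraction_threshold must lie in [0, 1]")
    frac = per_cpg_fraction(cs)
    idx = [i - 1 for i in cs.noti_cpg_indices]
    return bool(np.all(frac[idx] > clone_fraction_threshold))


def classify_concordance(array_call, bisulfite_methylated: bool) -> str:
    """Cross-classify an array call with the bisulfite verdict.

    MD + methylated  -> concordant_methylation
    MD + unmethylated -> discordant_deletion_likely (signal drop without
                         promoter methylation: deletion is the likely cause)
    RET + unmethylated -> concordant_retention
    RET + methylated, or any AD call -> discordant_other
    A no-data array call admits no verdict and raises.
    """
    call = CallState(array_call)
    if call is CallState.NODATA:
        raise ValidationError("no concordance verdict for a no-data array call")
    if call is CallState.MD:
        return "concordant_methylation" if bisulfite_methylated else "discordant_deletion_likely"
    if call is CallState.RET and not bisulfite_methylated:
        return "concordant_retention"
    return "discordant_other"
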