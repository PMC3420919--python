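"""GU-content profiling downstream of polyA signals and over whole 3'UTRs.

Efficient 3'-end processing needs, besides the signal hexamer, a GU-rich
element downstream of the cleavage site.  The local level is measured with a
5-nt window sliding over the 70 nt downstream of the signal's last base:
window ``i`` (1-based) covers downstream offsets ``[i, i + 4]``, and the
local GU level is the mean of windows 25-45, the region where real polyA
sites show elevated GU content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PROFILE_REGION = 70          # nt scanned downstream of the signal end
WINDOW = 5
N_WINDOWS = PROFILE_REGION - WINDOW + 1   # 66
LOCAL_FIRST = 25
LOCAL_LAST = 45
GU_RICH_THRESHOLD = 0.55


@dataclass
class GuProfile:
    window_props: list[float]        # window i (1-based) at index i-1
    local_level: float | None        # mean of windows 25-45; None if truncated
    gu_rich: bool | None
    truncated: bool = False


def _gu_fraction(seq: str) -> float:
    return sum(1 for b in seq if b in "GT") / len(seq)


def sliding_gu_profile(seq_downstream: str) -> list[float]:
    """GU fraction of each 5-nt window over the first 70 nt downstream.

    ``seq_downstream`` starts at the first base after the signal's last base
    (downstream offset 1).  Shorter sequences yield a truncated window list
    (only complete windows are reported).
    """
    if not seq_downstream:
        raise ValueError("empty downstream sequence")
    seq = seq_downstream[:PROFILE_REGION]
    return [
        _gu_fraction(seq[i : i + WINDOW]) for i in range(len(seq) - WINDOW + 1)
    ]


def local_gu_level(
    window_props: list[float], first: int = LOCAL_FIRST, last: int = LOCAL_LAST
) -> float | None:
    """Mean GU proportion over windows ``first``..``last`` (1-based).

    Returns None when window ``first`` itself is unavailable (sequence too
    short); if the tail is truncated the mean runs over the windows present.
    """
    if len(window_props) < first:
        return None
    avail = window_props[first - 1 : last]
    return float(np.mean(avail))


def is_gu_rich(level: float | None, threshold: float = GU_RICH_THRESHOLD) -> bool | None:
    """GU-rich iff strictly above the threshold (background is ~0.5)."""
    if level is None:
        return None
    return level > threshold


def gu_profile(seq_downstream: str, threshold: float = GU_RICH_THRESHOLD) -> GuProfile:
    props = sliding_gu_profile(seq_downstream)
    level = local_gu_level(props)
    return GuProfile(
        window_props=props,
        local_level=level,
        gu_rich=is_gu_rich(level, threshold),
        truncated=len(props) < N_WINDOWS,
    )


def global_gu_level(utr_seq: str) -> float:
    """Fraction of G+T bases over the whole spliced 3'UTR."""
    if not utr_seq:
        raise ValueError("empty UTR sequence")
    return _gu_fraction(utr_seq)


def annotate_candidates(candidates, utr_seqs, threshold: float = GU_RICH_THRESHOLD):
    """Fill GU fields of CandidateApaSnp records in place; returns them.

    The downstream sequence starts after the signal hexamer's last base on
    the spliced UTR of the signal-bearing allele (the single-base difference
    at the SNP never reaches offsets >= 25, but using the APA allele keeps
    the profile consistent with the site being scored).
    """
    for cand in candidates:
        utr = utr_seqs[cand.gene_id]
        apa_utr = utr[: cand.utr_offset] + cand.apa_allele + utr[cand.utr_offset + 1 :]
        sig_end = cand.utr_offset + (cand.change.signal_end_offset or 0)
        downstream = apa_utr[sig_end + 1 :]
        if downstream:
            prof = gu_profile(downstream, threshold)
            cand.local_gu_level = prof.local_level
            cand.gu_rich = prof.gu_rich
        cand.global_gu_level = global_gu_level(utr)
    return candidates
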