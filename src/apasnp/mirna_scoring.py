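"""Expression-weighted miRNA target-loss scoring of candidate APA-SNPs.

A proximal cleavage site at a candidate SNP removes the 3'UTR downstream of
the SNP, and with it any miRNA target sites there.  The "miRNA score
difference" quantifies that loss: target scores are computed on the short
3'UTR (stop codon to SNP) and the long one (full reference 3'UTR), averaged
per seed over mature miRNAs, weighted by the seed's share of cellular miRNA
expression, and differenced (long - short).  A high difference means the
proximal site would free the transcript from substantial miRNA repression.

The default site scorer is a canonical seed-match scorer: for each mature
miRNA it finds reverse-complement matches of the seed (positions 2-8) in
the UTR and sums the standard site-type weights (8mer 1.0, 7mer-m8 0.75,
7mer-A1 0.5, 6mer 0.25).  Any callable ``(utr, mature) -> float`` can be
substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .io_formats import normalize_sequence, reverse_complement

SITE_WEIGHTS = {"8mer": 1.0, "7mer-m8": 0.75, "7mer-A1": 0.5, "6mer": 0.25}


@dataclass
class MirnaSeedProfile:
    seed7: str
    matures: list[str] = field(default_factory=list)
    expression_proportion: float = 0.0


@dataclass
class MirnaScore:
    snp_id: str
    score_short: float
    score_long: float

    @property
    def score_diff(self) -> float:
        return self.score_long - self.score_short


def seed7_of(mature: str) -> str:
    """Seed sequence: mature miRNA positions 2-8."""
    mature = normalize_sequence(mature)
    if len(mature) < 8:
        raise ValueError("mature miRNA shorter than 8 nt")
    return mature[1:8]


def prepare_profile_sum_by_seed(mirna_table: pd.DataFrame) -> list[MirnaSeedProfile]:
    """Group matures by seed, sum expression, normalise to proportions.

    Rows need seed7, mature_seq and expression; zero-expression matures are
    dropped before grouping.
    """
    df = mirna_table[mirna_table["expression"] > 0]
    profiles = []
    for seed, grp in df.groupby("seed7"):
        profiles.append(
            MirnaSeedProfile(
                seed7=str(seed),
                matures=sorted(set(grp["mature_seq"])),
                expression_proportion=float(grp["expression"].sum()),
            )
        )
    total = sum(p.expression_proportion for p in profiles)
    if total <= 0:
        return []
    for p in profiles:
        p.expression_proportion /= total
    return profiles


def prepare_profile_probe_pipeline(
    probe_values: pd.DataFrame,
    probe_seed: dict[str, str],
    seed_matures: dict[str, list[str]],
    log_base: float = 2.0,
) -> list[MirnaSeedProfile]:
    """Seed profile from a log-scale probe expression matrix.

    Per probe, the mean over samples is taken; probes below the mean of
    those means are discarded; surviving probes map to seeds and their
    delogged values (log_base ** value) are summed per seed; seeds without a
    reference mature sequence are dropped; proportions are renormalised.
    """
    means = probe_values.mean(axis=1)
    cutoff = float(means.mean())
    kept = means[means >= cutoff]
    seed_sum: dict[str, float] = {}
    for probe, value in kept.items():
        seed = probe_seed.get(str(probe))
        if seed is None:
            continue
        seed_sum[seed] = seed_sum.get(seed, 0.0) + float(log_base ** value)
    profiles = [
        MirnaSeedProfile(seed7=s, matures=sorted(seed_matures[s]),
                         expression_proportion=v)
        for s, v in seed_sum.items()
        if s in seed_matures and seed_matures[s]
    ]
    total = sum(p.expression_proportion for p in profiles)
    if total <= 0:
        return []
    for p in profiles:
        p.expression_proportion /= total
    return profiles


def define_short_long(utr_seq: str, snp_utr_offset: int) -> tuple[str, str]:
    """Short UTR = spliced UTR up to and including the SNP; long = full UTR."""
    if not (0 <= snp_utr_offset < len(utr_seq)):
        raise ValueError("SNP offset outside the UTR")
    return utr_seq[: snp_utr_offset + 1], utr_seq


def default_seed_match_score(utr: str, mature: str) -> float:
    """Sum of canonical seed-site weights over all matches in the UTR.

    Site definitions (UTR read 5'->3'): the 6mer core is the reverse
    complement of seed positions 2-7; an additional match to position 8
    immediately 5' of the core and/or an adenine immediately 3' of it
    upgrade the site to 7mer-m8, 7mer-A1 or 8mer.
    """
    utr = normalize_sequence(utr)
    mature = normalize_sequence(mature)
    if len(mature) < 8:
        return 0.0
    core = reverse_complement(mature[1:7])      # seed positions 2-7
    m8 = reverse_complement(mature[7])          # complement of position 8
    score = 0.0
    start = utr.find(core)
    while start != -1:
        has_m8 = start > 0 and utr[start - 1] == m8
        end = start + len(core)
        has_a1 = end < len(utr) and utr[end] == "A"
        if has_m8 and has_a1:
            score += SITE_WEIGHTS["8mer"]
        elif has_m8:
            score += SITE_WEIGHTS["7mer-m8"]
        elif has_a1:
            score += SITE_WEIGHTS["7mer-A1"]
        else:
            score += SITE_WEIGHTS["6mer"]
        start = utr.find(core, start + 1)
    return score


def normalize_score(raw: float, utr_length: int, per_kb: bool = True) -> float:
    """Per-kilobase normalisation (default) or identity.

    Longer UTRs accumulate more sites by chance alone; dividing by length in
    kb makes short/long scores comparable.  A zero-length UTR scores 0.
    """
    if not per_kb:
        return raw
    if utr_length <= 0:
        return 0.0
    return raw / (utr_length / 1000.0)


def seed_and_weighted_score(
    utr: str,
    profiles: list[MirnaSeedProfile],
    scorer: Callable[[str, str], float] = default_seed_match_score,
    per_kb: bool = True,
) -> float:
    """Expression-weighted UTR target score over all expressed seeds.

    Per seed: mean score over its mature miRNAs; then the sum over seeds
    weighted by expression proportion.
    """
    total = 0.0
    for prof in profiles:
        if not prof.matures:
            continue
        per_mature = [
            normalize_score(scorer(utr, m), len(utr), per_kb) for m in prof.matures
        ]
        total += prof.expression_proportion * float(np.mean(per_mature))
    return total


def score_candidate(
    snp_id: str,
    utr_seq: str,
    snp_utr_offset: int,
    profiles: list[MirnaSeedProfile],
    scorer: Callable[[str, str], float] = default_seed_match_score,
    per_kb: bool = True,
) -> MirnaScore:
    short, long_ = define_short_long(utr_seq, snp_utr_offset)
    return MirnaScore(
        snp_id=snp_id,
        score_short=seed_and_weighted_score(short, profiles, scorer, per_kb),
        score_long=seed_and_weighted_score(long_, profiles, scorer, per_kb),
    )


def score_gene(scores: list[MirnaScore]) -> MirnaScore:
    """Mean over several transcript models of the same gene."""
    if not scores:
        raise ValueError("no transcript scores to average")
    return MirnaScore(
        snp_id=scores[0].snp_id,
        score_short=float(np.mean([s.score_short for s in scores])),
        score_long=float(np.mean([s.score_long for s in scores])),
    )


def classify_mirna_score(diffs: np.ndarray, cutoff: float | None = None) -> np.ndarray:
    """Split score differences into high/low at the run median (default).

    Strictly-above-cutoff is high; with all values equal everything is low.
    """
    diffs = np.asarray(diffs, dtype=float)
    if cutoff is None:
        cutoff = float(np.median(diffs))
    return np.where(diffs > cutoff, "high", "low")
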