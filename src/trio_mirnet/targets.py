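"""Plant-style miRNA target prediction by complementarity scoring.

Plant miRNAs guide cleavage of near-perfectly complementary sites, so target
prediction reduces to scoring the miRNA/site duplex position by position with
the Allen-type rule set: a Watson-Crick match costs 0, a G:U wobble 0.5 and a
mismatch 1.0, with penalties doubled across miRNA positions 2-13 (the seed
and central region whose pairing is required for slicing). A site passes when
the summed penalty is at or below ``max_score`` (default 4.5). Duplexes are
gapless: the dominant plant cleavage-site geometry, and it keeps exhaustive
window scanning exact.

The cleavage position reported for each site is the transcript nucleotide
opposite miRNA position 10, the 10-11 duplex centre where ARGONAUTE cuts;
degradome tags pile up there when the site is used in vivo.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .types import TargetSite

#: 1-based miRNA positions whose penalties are doubled by default.
DEFAULT_CORE_RANGE = (2, 13)
DEFAULT_MAX_SCORE = 4.5

_BASES = "ACGU"
_ENCODE = {b: i for i, b in enumerate(_BASES)}
_ENCODE["T"] = _ENCODE["U"]

# penalty[mirna_base, target_base]; A:U / C:G match, G:U wobble (either order)
_PAIR_PENALTY = np.ones((4, 4))
for _m, _t in (("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")):
    _PAIR_PENALTY[_ENCODE[_m], _ENCODE[_t]] = 0.0
_PAIR_PENALTY[_ENCODE["G"], _ENCODE["U"]] = 0.5
_PAIR_PENALTY[_ENCODE["U"], _ENCODE["G"]] = 0.5

_STATE_BY_PENALTY = {0.0: "match", 0.5: "GU", 1.0: "mismatch"}

_COMPLEMENT = str.maketrans("ACGUT", "UGCAA")


def encode_rna(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string as integers (T read as U)."""
    try:
        return np.fromiter(
            (_ENCODE[b] for b in seq.upper()), dtype=np.int8, count=len(seq)
        )
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc.args[0]!r} in sequence") from exc


def reverse_complement(seq: str) -> str:
    """Reverse complement in RNA alphabet (T accepted on input)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def position_weights(
    length: int, core_range: Optional[tuple[int, int]] = DEFAULT_CORE_RANGE
) -> np.ndarray:
    """Per-miRNA-position penalty multipliers (1-based core range doubled)."""
    w = np.ones(length)
    if core_range is not None:
        lo, hi = core_range
        w[max(lo - 1, 0) : hi] = 2.0
    return w


def score_duplex(
    mirna_seq: str,
    site_seq: str,
    core_range: Optional[tuple[int, int]] = DEFAULT_CORE_RANGE,
    mirna_id: str = "",
    transcript_id: str = "",
    site_start: int = 1,
) -> TargetSite:
    """Score a gapless miRNA/site duplex.

    ``site_seq`` is given 5'->3' as it reads on the transcript; the miRNA
    binds antiparallel, so miRNA position 1 pairs the site's 3'-most base.
    Both sequences must have equal length. ``core_range=None`` disables the
    positional doubling (uniform weights), which makes the score symmetric
    under exchanging the two strands.
    """
    if len(mirna_seq) != len(site_seq):
        raise ValueError(
            f"gapless duplex requires equal lengths "
            f"({len(mirna_seq)} vs {len(site_seq)})"
        )
    m = encode_rna(mirna_seq)
    t = encode_rna(site_seq)[::-1]  # index i = target base opposite miRNA pos i+1
    penalties = _PAIR_PENALTY[m, t]
    weights = position_weights(len(m), core_range)
    states = tuple(_STATE_BY_PENALTY[p] for p in penalties)
    length = len(m)
    return TargetSite(
        mirna_id=mirna_id,
        transcript_id=transcript_id,
        site_start=site_start,
        site_end=site_start + length - 1,
        score=float(np.dot(penalties, weights)),
        cleavage_pos=site_start + length - 10,
        per_position_state=states,
    )


def _window_scores(
    mirna: np.ndarray, transcript: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Vector of duplex scores for every window of len(mirna) on transcript."""
    length = len(mirna)
    windows = np.lib.stride_tricks.sliding_window_view(transcript, length)
    # window slot j holds the target base opposite miRNA position L - j
    m_rev = mirna[::-1]
    w_rev = weights[::-1]
    return _PAIR_PENALTY[m_rev[None, :], windows] @ w_rev


def scan_transcript(
    mirna_seq: str,
    transcript_seq: str,
    max_score: float = DEFAULT_MAX_SCORE,
    core_range: Optional[tuple[int, int]] = DEFAULT_CORE_RANGE,
    mirna_id: str = "",
    transcript_id: str = "",
) -> list[TargetSite]:
    """All candidate sites for one miRNA on one transcript.

    Slides a gapless window across the transcript, scores every window and
    reports those with score <= ``max_score`` (overlaps allowed), ordered by
    score then coordinate.
    """
    length = len(mirna_seq)
    if len(transcript_seq) < length:
        raise ValueError("transcript shorter than the miRNA")
    m = encode_rna(mirna_seq)
    t = encode_rna(transcript_seq)
    weights = position_weights(length, core_range)
    scores = _window_scores(m, t, weights)
    hits = np.flatnonzero(scores <= max_score)
    sites = [
        score_duplex(
            mirna_seq,
            transcript_seq[i : i + length],
            core_range=core_range,
            mirna_id=mirna_id,
            transcript_id=transcript_id,
            site_start=i + 1,
        )
        for i in hits
    ]
    sites.sort(key=lambda s: (s.score, s.site_start))
    return sites


def scan_many(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    max_score: float = DEFAULT_MAX_SCORE,
    core_range: Optional[tuple[int, int]] = DEFAULT_CORE_RANGE,
) -> list[TargetSite]:
    """Candidate sites for every miRNA against every transcript.

    Window scoring is vectorised per (miRNA, transcript) pair; full duplex
    records are only materialised for windows passing the threshold, so the
    all-against-all scan stays fast at realistic catalogue sizes.
    """
    encoded_tx = {tid: encode_rna(seq) for tid, seq in transcripts.items()}
    out: list[TargetSite] = []
    for mid, mseq in mirnas.items():
        m = encode_rna(mseq)
        weights = position_weights(len(m), core_range)
        for tid, t in encoded_tx.items():
            if len(t) < len(m):
                continue
            scores = _window_scores(m, t, weights)
            for i in np.flatnonzero(scores <= max_score):
                out.append(
                    score_duplex(
                        mseq,
                        transcripts[tid][i : i + len(m)],
                        core_range=core_range,
                        mirna_id=mid,
                        transcript_id=tid,
                        site_start=int(i) + 1,
                    )
                )
    out.sort(key=lambda s: (s.mirna_id, s.transcript_id, s.score, s.site_start))
    return out


def sites_to_frame(sites: Sequence[TargetSite]):
    """Tabulate sites as the candidate-site TSV layout."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "mirna_id": s.mirna_id,
                "transcript_id": s.transcript_id,
                "site_start": s.site_start,
                "site_end": s.site_end,
                "score": s.score,
                "cleavage_pos": s.cleavage_pos,
                "alignment": "".join(
                    {"match": "|", "GU": "o", "mismatch": "."}[st]
                    for st in s.per_position_state
                ),
            }
            for s in sites
        ],
        columns=[
            "mirna_id",
            "transcript_id",
            "site_start",
            "site_end",
            "score",
            "cleavage_pos",
            "alignment",
        ],
    )
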