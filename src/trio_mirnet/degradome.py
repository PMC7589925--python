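"""Degradome t-plots, category 0-4 site classification and differential
degradation.

Degradome (PARE) sequencing captures the 5' ends of uncapped mRNA fragments;
miRNA-guided cleavage leaves a diagnostic pile-up of 5' tags at the duplex
centre. A t-plot is the per-position tag-count profile of one transcript,
and a predicted cleavage site is classified by where its tag count sits in
that profile:

  category 0 - count > 1, the unique maximum of the profile (highest
               confidence);
  category 1 - count > 1, equal to a maximum attained at more than one
               position;
  category 2 - count > 1, below the maximum but above the median;
  category 3 - count > 1, at or below the median;
  category 4 - exactly one tag;
  none       - no tag at the site (the site fails validation).

The maximum and median are taken over positions with nonzero counts only;
including structural zeros would make category 2 nearly unattainable on long
transcripts. Raw integer counts drive category calls; per-library tag-RPM
normalization is used only for differential-degradation testing.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .expression import test_differential
from .types import AbundanceMatrix, CategorizedSite, DegradomeProfile, TargetSite

logger = logging.getLogger(__name__)


def build_tplot(
    tags: Iterable[tuple[int, int]],
    transcript_id: str,
    length: int,
    library_id: str = "",
) -> DegradomeProfile:
    """Aggregate (position, count) tag records into a dense t-plot.

    Records at the same position sum; total tags are conserved.
    """
    counts = np.zeros(length, dtype=np.int64)
    for pos, n in tags:
        if not (1 <= pos <= length):
            raise ValueError(
                f"tag position {pos} outside 1..{length} on {transcript_id}"
            )
        if n < 0:
            raise ValueError("negative tag count")
        counts[pos - 1] += n
    return DegradomeProfile(
        transcript_id=transcript_id, length=length, counts=counts,
        library_id=library_id,
    )


def assign_category(
    profile: DegradomeProfile, cleavage_pos: int
) -> Optional[int]:
    """Category 0-4 call for a cleavage position, or None without tag support."""
    c = profile.count_at(cleavage_pos)
    if c == 0:
        return None
    if c == 1:
        return 4
    nonzero = profile.counts[profile.counts > 0]
    maximum = int(nonzero.max())
    if c == maximum:
        return 0 if int((nonzero == maximum).sum()) == 1 else 1
    if c > float(np.median(nonzero)):
        return 2
    return 3


def validate_sites(
    candidate_sites: Sequence[TargetSite],
    profiles: Iterable[DegradomeProfile],
    max_category: int = 4,
) -> list[CategorizedSite]:
    """Keep candidate sites supported by degradome evidence.

    A site is retained when its category is <= ``max_category`` in at least
    one library; the best (lowest) category and the library attaining it are
    recorded. Candidates on transcripts absent from the profiles are dropped
    with a warning.
    """
    by_transcript: dict[str, list[DegradomeProfile]] = {}
    for prof in profiles:
        by_transcript.setdefault(prof.transcript_id, []).append(prof)

    kept: list[CategorizedSite] = []
    for site in candidate_sites:
        profs = by_transcript.get(site.transcript_id)
        if not profs:
            logger.warning(
                "no degradome profile for transcript %s; dropping site %s@%d",
                site.transcript_id, site.mirna_id, site.site_start,
            )
            continue
        best: Optional[CategorizedSite] = None
        for prof in profs:
            cat = assign_category(prof, site.cleavage_pos)
            if cat is None or cat > max_category:
                continue
            if best is None or cat < best.category:
                best = CategorizedSite(
                    site=site,
                    tag_count=prof.count_at(site.cleavage_pos),
                    category=cat,
                    library_id=prof.library_id,
                )
        if best is not None:
            kept.append(best)
    return kept


def site_tag_matrix(
    sites: Sequence[TargetSite],
    profiles: Iterable[DegradomeProfile],
    meta: pd.DataFrame,
) -> AbundanceMatrix:
    """Raw tag counts at each site's cleavage position, per library.

    Rows are sites keyed "mirna|transcript|cleavage_pos"; columns follow
    ``meta`` (indexed by library_id). Missing (transcript, library) profiles
    count as zero.
    """
    lookup: dict[tuple[str, str], DegradomeProfile] = {}
    for prof in profiles:
        lookup[(prof.transcript_id, prof.library_id)] = prof
    lib_ids = list(meta.index)
    rows = {}
    for site in sites:
        key = f"{site.mirna_id}|{site.transcript_id}|{site.cleavage_pos}"
        rows[key] = [
            lookup[(site.transcript_id, lib)].count_at(site.cleavage_pos)
            if (site.transcript_id, lib) in lookup
            else 0
            for lib in lib_ids
        ]
    values = pd.DataFrame.from_dict(rows, orient="index", columns=lib_ids)
    return AbundanceMatrix(values=values, meta=meta, unit="raw_count")


def normalize_tag_rpm(
    matrix: AbundanceMatrix, library_totals: Mapping[str, int]
) -> AbundanceMatrix:
    """Tags-per-million over each library's *total* degradome tag count.

    Site-level matrices cover only cleavage positions, so per-library totals
    must come from the full profiles, not the matrix columns.
    """
    totals = pd.Series(library_totals, dtype=float).reindex(matrix.values.columns)
    if totals.isna().any() or (totals <= 0).any():
        bad = list(totals.index[totals.isna() | (totals <= 0)])
        raise ValueError(f"invalid degradome totals for libraries: {bad}")
    return AbundanceMatrix(
        values=matrix.values / totals * 1e6, meta=matrix.meta, unit="RPM"
    )


def test_differential_degradation(
    site_matrix: AbundanceMatrix,
    groups: Mapping[str, Sequence[str]],
    library_totals: Mapping[str, int],
    pseudocount: float = 1.0,
    contrast: Optional[str] = None,
) -> pd.DataFrame:
    """Differential degradation of target sites between library groups.

    Normalizes site tag counts to tags-per-million per library, then applies
    the same Welch t / ANOVA contract as expression-level testing.
    """
    rpm = normalize_tag_rpm(site_matrix, library_totals)
    return test_differential(
        rpm, groups, method="auto", pseudocount=pseudocount, contrast=contrast
    )
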