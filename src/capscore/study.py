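"""Published evaluation counts for the 95-patient CAP study cohort.

The patient-level data behind the published evaluation were never deposited,
but every accuracy metric is recomputable from the counts the report prints:
cohort size, total events, number classed severe, and events within the
severe group, per criterion and outcome.  This module carries those counts
and rebuilds the 2×2 tables, so the diagnostics pipeline can reproduce the
published tables exactly.

Two analysis subsets exist because one (different) patient was dropped from
each arm for missing data: the CURB-65/CURSI/CURASI arm has 8 deaths and 11
composite (death-or-ICU) events among n=95; the CRB-65/CRSI/CRASI arm has
8 deaths and 12 composite events among n=95.

Note one internal inconsistency in the source report: its CRB-65 mortality
column (sensitivity 50.0% of 8 deaths, specificity 91.9%) implies 4 deaths
in the severe group, while its figure narrative says 3 died.  The counts
here follow the printed table arithmetic (4), which is self-consistent
across all four metrics of that column.
"""

from __future__ import annotations

from typing import Mapping

from .diagnostics import ConfusionTable, OutcomeKind
from .scoring import CriterionName

__all__ = ["STUDY_N", "STUDY_TABLES", "study_confusion_table"]

STUDY_N = 95

# (criterion, outcome) -> (n_events, n_severe, events_in_severe)
_PRINTED_COUNTS: Mapping[tuple[CriterionName, OutcomeKind], tuple[int, int, int]] = {
    (CriterionName.CURB65, OutcomeKind.death): (8, 28, 7),
    (CriterionName.CURSI, OutcomeKind.death): (8, 31, 7),
    (CriterionName.CURASI, OutcomeKind.death): (8, 31, 7),
    (CriterionName.CURB65, OutcomeKind.death_or_icu): (11, 28, 8),
    (CriterionName.CURSI, OutcomeKind.death_or_icu): (11, 31, 9),
    (CriterionName.CURASI, OutcomeKind.death_or_icu): (11, 31, 9),
    (CriterionName.CRB65, OutcomeKind.death): (8, 11, 4),
    (CriterionName.CRSI, OutcomeKind.death): (8, 20, 6),
    (CriterionName.CRASI, OutcomeKind.death): (8, 19, 6),
    (CriterionName.CRB65, OutcomeKind.death_or_icu): (12, 11, 4),
    (CriterionName.CRSI, OutcomeKind.death_or_icu): (12, 20, 7),
    (CriterionName.CRASI, OutcomeKind.death_or_icu): (12, 19, 7),
}


def study_confusion_table(
    criterion: CriterionName, outcome_kind: OutcomeKind
) -> ConfusionTable:
    """Rebuild the published 2×2 table for one criterion/outcome pair.

    From the printed counts (events E, severe S, events-in-severe T among
    n=95): tp = T, fn = E − T, fp = S − T, tn = n − E − fp.
    """
    events, severe, tp = _PRINTED_COUNTS[(CriterionName(criterion), outcome_kind)]
    fn = events - tp
    fp = severe - tp
    tn = STUDY_N - events - fp
    return ConfusionTable(tp=tp, fn=fn, fp=fp, tn=tn, excluded=0)


STUDY_TABLES: Mapping[tuple[CriterionName, OutcomeKind], ConfusionTable] = {
    key: study_confusion_table(*key) for key in _PRINTED_COUNTS
}
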