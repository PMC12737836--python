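"""Agreement between two genotype call sets for the same accession.

Used to validate in-silico calls from a genome assembly against wet-lab
array calls for the same biological accession. Calls are compared at the
IUPAC-code level over the markers both sets share; pairs where either call
is missing are excluded from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .iupac import MISSING, site_score


@dataclass(frozen=True)
class ConcordanceReport:
    sample_pair: tuple[str, str]
    n_shared_markers: int
    n_compared: int
    n_matching: int
    percent: float


def concordance(
    calls1: pd.Series,
    calls2: pd.Series,
    partial_credit: bool = False,
) -> ConcordanceReport:
    """Percent of shared, both-called markers with identical calls.

    With ``partial_credit`` a heterozygous call sharing one allele with a
    homozygous call scores 0.5 instead of 0 (off by default: identity is
    at the code level).
    """
    shared = calls1.index.intersection(calls2.index)
    if len(shared) == 0:
        raise ValueError("no shared markers between the two call sets")
    a = calls1.loc[shared]
    b = calls2.loc[shared]
    both = (a != MISSING) & (b != MISSING)
    a, b = a[both], b[both]
    n_compared = int(both.sum())
    if partial_credit:
        matching = sum(site_score(x, y) for x, y in zip(a, b))
    else:
        matching = int((a == b).sum())
    percent = 100.0 * matching / n_compared if n_compared else float("nan")
    return ConcordanceReport(
        sample_pair=(str(calls1.name), str(calls2.name)),
        n_shared_markers=len(shared),
        n_compared=n_compared,
        n_matching=int(matching) if not partial_credit else matching,
        percent=percent,
    )


def concordance_table(
    matrix1: pd.DataFrame, matrix2: pd.DataFrame, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Per-pair concordance reports as a table."""
    rows = []
    for s1, s2 in pairs:
        rep = concordance(matrix1[s1], matrix2[s2])
        rows.append(
            (s1, s2, rep.n_shared_markers, rep.n_compared, rep.n_matching, rep.percent)
        )
    return pd.DataFrame(
        rows,
        columns=["sample1", "sample2", "n_shared", "n_compared", "n_matching", "percent"],
    )
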