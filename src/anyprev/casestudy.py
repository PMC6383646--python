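"""Bundled case study: peripartum prevalence of six anxiety and related disorders.

Twenty samples from 18 articles (10,033 participants) reporting the prevalence
of at least one of panic disorder, obsessive-compulsive disorder, generalized
anxiety disorder, social phobia, specific phobia, and posttraumatic stress
disorder.  The source articles print percentages; counts are reconstructed as
``round(prevalence% * N / 100)`` (half away from zero), which is exact to the
printed precision.  Two parent studies contributed both a pregnant and a
postpartum sample; those pairs share a cluster label.  Seven samples also
contributed individual-participant data (IPD) to the original analysis; the
raw IPD are not redistributable, so the fixture records only an
``ipd_available`` flag alongside the aggregate counts.
"""

from __future__ import annotations

from .data import AggregateSample, DisorderPanel, MetaDataset

__all__ = ["CASE_STUDY_PANEL", "case_study_table1"]

CASE_STUDY_PANEL = DisorderPanel(
    ["panic", "ocd", "gad", "social_phobia", "specific_phobia", "ptsd"]
)

# sample_id, cluster_id, N, any%, panic%, ocd%, gad%, social%, specific%, ptsd%, ipd
_ROWS = [
    ("Zar 2002",            "Zar 2002",     453,  21.9, 1.3,  0.2,  0.9,  2.7,  18.3, 1.3,  True),
    ("Wenzel 2003",         "Wenzel 2003",  68,   4.4,  None, None, 4.4,  None, None, None, False),
    ("Wenzel 2005",         "Wenzel 2005",  147,  None, 1.4,  2.7,  8.2,  4.1,  None, None, False),
    ("Uguz 2007",           "Uguz 2007",    434,  3.5,  None, 3.5,  None, None, None, None, False),
    ("Rogal 2007",          "Rogal 2007",   1100, 3.0,  None, None, None, None, None, 3.0,  False),
    ("Mota 2008 (Preg.)",   "Mota 2008",    451,  13.2, 2.1,  None, 1.9,  3.3,  9.3,  None, False),
    ("Mota 2008 (Post.)",   "Mota 2008",    1061, 15.0, 4.0,  None, 2.3,  2.5,  10.2, None, False),
    ("Seng 2009",           "Seng 2009",    1581, 7.9,  None, None, None, None, None, 7.9,  False),
    ("Kersting 2009",       "Kersting 2009", 65,  0.0,  0.0,  0.0,  None, None, 0.0,  0.0,  False),
    ("Fisher 2010a (Preg.)", "Fisher 2010a", 199, None, 1.5,  None, 10.6, None, None, None, False),
    ("Fisher 2010a (Post.)", "Fisher 2010a", 165, None, 4.2,  None, 11.5, None, None, None, False),
    ("Chaudron 2010",       "Chaudron 2010", 24,  37.5, 4.2,  29.2, None, None, 8.3,  8.3,  True),
    ("Fisher 2010b",        "Fisher 2010b", 196,  8.7,  0.0,  None, 2.6,  3.6,  3.6,  None, True),
    ("Uguz 2010",           "Uguz 2010",    309,  15.5, 1.9,  5.2,  3.6,  3.2,  3.2,  0.0,  False),
    ("Matthey 2011",        "Matthey 2011", 171,  14.0, 2.9,  2.9,  11.1, 4.1,  None, 0.6,  True),
    ("Prenoveau 2013",      "Prenoveau 2013", 2202, 5.5, None, None, 5.5, None, None, None, False),
    ("Fadzil 2013",         "Fadzil 2013",  175,  6.3,  5.7,  0.0,  0.0,  0.6,  None, 0.0,  True),
    ("Kim 2015",            "Kim 2015",     745,  6.6,  None, None, None, None, None, 6.6,  False),
    ("Usuda 2016",          "Usuda 2016",   177,  3.4,  1.1,  1.7,  0.0,  1.1,  None, 0.6,  True),
    ("Fairbrother 2016",    "Fairbrother 2016", 310, 15.2, 0.7, 3.6, 3.2, 5.2,  7.4,  0.7,  True),
]


def _count(pct: float | None, N: int) -> int | None:
    if pct is None:
        return None
    return int((pct * N / 100.0) + 0.5)  # half away from zero; no exact ties occur


def case_study_table1() -> MetaDataset:
    """The case-study dataset with counts reconstructed from printed percentages."""
    samples = []
    for sid, cid, N, any_pct, *pcts, ipd in _ROWS:
        samples.append(
            AggregateSample(
                sample_id=sid,
                cluster_id=cid,
                N=N,
                counts=tuple(_count(p, N) for p in pcts),
                any_count=_count(any_pct, N),
                ipd_available=ipd,
            )
        )
    return MetaDataset(CASE_STUDY_PANEL, samples)
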