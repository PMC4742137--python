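"""Multi-sample overlap: sites shared by every sample with the identical
substitution, per-sample unique sites, and the substitution-type histogram.

Overlap identity is the plus-strand key (chrom, pos, ref, alt) so that
strand-unknown sites compare consistently across samples; "unique" means
present in exactly one sample, not merely absent from the overlap.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping

import pandas as pd

from .seqs import CANONICAL_TYPES, SUBSTITUTION_TYPES

KEY = ["chrom", "pos", "ref", "alt"]


def _keyset(calls: pd.DataFrame, sample_id: str) -> set[tuple]:
    keys = list(map(tuple, calls[KEY].itertuples(index=False)))
    pos_keys = {(k[0], k[1]) for k in keys}
    if len(pos_keys) != len(keys):
        raise ValueError(f"sample {sample_id}: duplicate (chrom, pos) entries")
    return set(keys)


def intersect_samples(cohort: Mapping[str, pd.DataFrame]
                      ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Sites present in every sample with the same (ref, alt), plus the
    sites private to each single sample.

    Returns (overlap, uniques); overlap rows carry the per-site fields of
    the first sample's call (depths and frequencies are sample-specific and
    are not merged).
    """
    if not cohort:
        raise ValueError("cohort must contain at least one sample")
    keysets = {s: _keyset(df, s) for s, df in cohort.items()}
    shared = set.intersection(*keysets.values())

    counts: Counter = Counter()
    for ks in keysets.values():
        counts.update(ks)
    n = len(cohort)

    first_sample = next(iter(cohort))
    first = cohort[first_sample]
    in_overlap = first[KEY].apply(tuple, axis=1).isin(shared) \
        if len(first) else pd.Series([], dtype=bool)
    overlap = first[in_overlap].reset_index(drop=True) if len(first) else first

    uniques = {}
    for s, df in cohort.items():
        if len(df) == 0:
            uniques[s] = df
            continue
        mine = df[KEY].apply(tuple, axis=1)
        only_here = mine.map(lambda k: counts[k] == 1 and (n == 1 or k not in shared))
        uniques[s] = df[only_here].reset_index(drop=True)
    return overlap, uniques


def tabulate_substitutions(calls: pd.DataFrame,
                           column: str = "substitution_stranded") -> pd.DataFrame:
    """Histogram over the 12 substitution types with the canonical split.

    Returns a frame indexed by type with columns count, percent (of total,
    2 decimals) and canonical flag; all 12 types appear even at count 0.
    """
    counts = Counter(calls[column]) if len(calls) else Counter()
    unknown = set(counts) - set(SUBSTITUTION_TYPES)
    if unknown:
        raise ValueError(f"unrecognized substitution types: {sorted(unknown)}")
    total = sum(counts.values())
    rows = []
    for t in SUBSTITUTION_TYPES:
        c = counts.get(t, 0)
        rows.append([t, c, round(100 * c / total, 2) if total else 0.0,
                     t in CANONICAL_TYPES])
    return pd.DataFrame(rows, columns=["substitution", "count", "percent",
                                       "canonical"]).set_index("substitution")


def canonical_split(table: pd.DataFrame) -> dict[str, int]:
    """Totals from a tabulate_substitutions frame."""
    canon = int(table.loc[table["canonical"], "count"].sum())
    total = int(table["count"].sum())
    return {"canonical": canon, "non_canonical": total - canon, "total": total}
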