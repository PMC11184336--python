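"""Per-mutation enrichment statistics between naive and sorted populations.

For each designed mutation, with mutant/wild-type read counts at its codon
position in the naive (preselection) and sorted populations:

    F   = Reads_mut / (Reads_mut + Reads_wt)          (per population)
    E   = F_sort / F_naive                            (crude enrichment)
    WES = ln(E) * sqrt(Reads_mut,sort + Reads_mut,naive)

The square-root weight upweights mutations that were well sampled, so a
mutation seen in many reads needs a smaller frequency shift to score than
one seen in a handful.  Reads whose codon at a position matches neither the
wild-type nor the designed codon (OTHER) are excluded from that position's
denominator.

The printed formulas are undefined on zero counts; an optional pseudocount
``alpha`` is applied inside F only (the weight term always uses raw mutant
counts), with ``alpha = 0`` reproducing the literal formulas and raising on
zeros.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from tnevolve.design import MutationLibraryDesign


class UndefinedFrequencyError(ZeroDivisionError):
    """Both counts zero with no pseudocount."""


def mutation_frequency(reads_mut: int, reads_wt: int, pseudocount: float = 0.0) -> float:
    """Mutant-allele frequency F = (mut + a) / (mut + wt + 2a)."""
    if reads_mut < 0 or reads_wt < 0:
        raise ValueError("read counts must be >= 0")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    denom = reads_mut + reads_wt + 2.0 * pseudocount
    if denom == 0:
        raise UndefinedFrequencyError(
            "both counts zero; use a pseudocount to define F"
        )
    return (reads_mut + pseudocount) / denom


def crude_enrichment(f_sort: float, f_naive: float) -> float:
    """Crude enrichment E = F_sort / F_naive."""
    for f in (f_sort, f_naive):
        if not 0.0 <= f <= 1.0:
            raise ValueError("frequencies must be in [0, 1]")
    if f_naive == 0:
        raise ZeroDivisionError(
            "F_naive is 0; recompute frequencies with a pseudocount"
        )
    return f_sort / f_naive


def weighted_enrichment(e: float, reads_mut_sort: int, reads_mut_naive: int) -> float:
    """Weighted enrichment score WES = ln(E) * sqrt(mut_sort + mut_naive)."""
    if e <= 0:
        raise ValueError("E must be > 0; apply a pseudocount upstream")
    if reads_mut_sort < 0 or reads_mut_naive < 0:
        raise ValueError("read counts must be >= 0")
    return math.log(e) * math.sqrt(reads_mut_sort + reads_mut_naive)


def _counts_by_id(counts: pd.DataFrame, design: MutationLibraryDesign, what: str) -> pd.DataFrame:
    required = {"mutation_id", "mut", "wt"}
    if not required <= set(counts.columns):
        raise ValueError(f"{what} counts need columns {sorted(required)}")
    unknown = set(counts["mutation_id"]) - set(design.ids)
    if unknown:
        raise KeyError(f"{what} counts contain ids absent from the design: {sorted(unknown)}")
    return counts.set_index("mutation_id")


def enrichment_table(
    naive_counts: pd.DataFrame,
    sorted_counts: pd.DataFrame,
    design: MutationLibraryDesign,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Full per-mutation enrichment table, ranked by WES descending.

    One row per designed amino-acid substitution; mutations missing from a
    count table get zero counts.  Detection is codon-exact upstream, but two
    designed codons encoding the same amino-acid change at the same position
    would share one row (ids encode the substitution).  Rows where WES is
    undefined (zero counts with ``pseudocount = 0``) are kept and flagged
    rather than dropped.  Ties in WES are broken by mutation id.
    """
    nc = _counts_by_id(naive_counts, design, "naive")
    sc = _counts_by_id(sorted_counts, design, "sorted")
    rows = []
    for mid in design.ids:
        mn = int(nc["mut"].get(mid, 0))
        wn = int(nc["wt"].get(mid, 0))
        ms = int(sc["mut"].get(mid, 0))
        ws = int(sc["wt"].get(mid, 0))
        try:
            f_naive = mutation_frequency(mn, wn, pseudocount)
            f_sort = mutation_frequency(ms, ws, pseudocount)
            e = crude_enrichment(f_sort, f_naive)
            wes = weighted_enrichment(e, ms, mn) if e > 0 else None
            flagged = False
        except (UndefinedFrequencyError, ZeroDivisionError, ValueError):
            f_naive = f_sort = e = wes = None
            flagged = True
        if e == 0.0:  # fully depleted: ln undefined, flag instead
            wes, flagged = None, True
        rows.append((mid, mn, wn, ms, ws, f_naive, f_sort, e, wes, flagged))
    df = pd.DataFrame(
        rows,
        columns=[
            "mutation_id",
            "reads_mut_naive",
            "reads_wt_naive",
            "reads_mut_sort",
            "reads_wt_sort",
            "F_naive",
            "F_sort",
            "E",
            "WES",
            "flagged",
        ],
    )
    df = df.sort_values(
        ["WES", "mutation_id"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def enrichment_summary(table: pd.DataFrame, top_n: int = 10) -> dict:
    scored = table.dropna(subset=["WES"])
    return {
        "n_mutations": int(len(table)),
        "n_scored": int(len(scored)),
        "n_flagged": int(table["flagged"].sum()),
        "top": [
            {"mutation_id": r.mutation_id, "WES": float(r.WES), "E": float(r.E)}
            for r in scored.head(top_n).itertuples()
        ],
    }
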