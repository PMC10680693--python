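"""GSEA post-processing: NES direction switches between two treatments.

Input tables are per-condition GSEA outputs (term, library, NES, padj).
The analysis keeps significant terms, finds terms whose normalized
enrichment score (NES) flips sign between the two conditions, ranks them
by delta-NES = |NES_A - NES_B| (for a sign flip this is at least the
larger magnitude), and classifies term names by keyword category
(e.g. breast / prostate / nuclear receptor / MYC) with a word-frequency
summary of the switching term names.
"""

from __future__ import annotations

import re
from collections import Counter

import pandas as pd

NES_COLUMNS = ("term", "NES", "padj")

#: Default keyword map. GSEA term names rarely contain the literal phrase
#: "nuclear receptor", so that category matches receptor-related tokens.
DEFAULT_KEYWORDS: dict[str, list[str]] = {
    "MYC": ["MYC"],
    "breast": ["BREAST", "MAMMARY", "BRCA"],
    "prostate": ["PROSTATE", "LNCAP", "ANDROGEN"],
    "nuclear receptor": [
        "ESTROGEN",
        "ANDROGEN",
        "RECEPTOR",
        "ESR",
        "AR_",
        "NUCLEAR_RECEPTOR",
        "STEROID",
    ],
}


def _check_table(records: pd.DataFrame) -> None:
    missing = [c for c in NES_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"NES table missing columns {missing}")
    if records["term"].duplicated().any():
        dups = records.loc[records["term"].duplicated(), "term"].tolist()
        raise ValueError(f"duplicate terms within one condition: {dups[:5]}")


def filter_significant(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Keep records with adjusted p below *alpha*."""
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    _check_table(records)
    return records[records["padj"] < alpha].reset_index(drop=True)


def find_switches(
    cond_a: pd.DataFrame, cond_b: pd.DataFrame
) -> pd.DataFrame:
    """Terms whose NES sign is strictly opposite between two conditions.

    Both inputs should already be significance-filtered. The join is on
    term; NES exactly 0 has no sign and never switches. Returns columns
    term, nes_a, nes_b, delta_nes with delta_nes = |nes_a - nes_b|, sorted
    by descending delta_nes (ties alphabetically by term).
    """
    _check_table(cond_a)
    _check_table(cond_b)
    merged = cond_a.merge(cond_b, on="term", suffixes=("_a", "_b"))
    flips = merged[
        (merged["NES_a"] * merged["NES_b"] < 0)
        & (merged["NES_a"] != 0)
        & (merged["NES_b"] != 0)
    ].copy()
    out = pd.DataFrame(
        {
            "term": flips["term"],
            "nes_a": flips["NES_a"],
            "nes_b": flips["NES_b"],
            "delta_nes": (flips["NES_a"] - flips["NES_b"]).abs(),
        }
    )
    return (
        out.sort_values(["delta_nes", "term"], ascending=[False, True],
                        kind="mergesort")
        .reset_index(drop=True)
    )


def classify_terms(
    switches: pd.DataFrame,
    keyword_map: dict[str, list[str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keyword classification of switching terms + word-frequency table.

    Keywords are matched case-insensitively as substrings of the term
    name; the first matching category in the declared order of
    ``keyword_map`` wins; unmatched terms get category ``"other"``.
    Also returns token frequencies across all switching term names
    (tokens split on non-alphanumeric characters).
    """
    if keyword_map is None:
        keyword_map = DEFAULT_KEYWORDS
    if not keyword_map:
        raise ValueError("keyword map must be non-empty")

    def categorize(term: str) -> str:
        upper = term.upper()
        for category, words in keyword_map.items():
            if any(w.upper() in upper for w in words):
                return category
        return "other"

    classified = switches.copy()
    classified["category"] = [categorize(t) for t in classified["term"]]

    tokens = Counter()
    for term in classified["term"]:
        tokens.update(t for t in re.split(r"[^A-Za-z0-9]+", term.upper()) if t)
    freq = pd.DataFrame(
        sorted(tokens.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["token", "count"],
    )
    return classified, freq


def top_terms(switches: pd.DataFrame, n: int = 40) -> pd.DataFrame:
    """Top *n* switching terms by descending delta-NES (ties by term name)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    ranked = switches.sort_values(
        ["delta_nes", "term"], ascending=[False, True], kind="mergesort"
    )
    return ranked.head(n).reset_index(drop=True)
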