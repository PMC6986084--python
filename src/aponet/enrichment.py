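"""GO over-representation analysis: one-sided hypergeometric test + Bonferroni.

For a study set of n annotated transcripts drawn from a background of N,
a term annotating K background transcripts and k study transcripts is scored
with the upper-tail hypergeometric probability

    p_raw = P(X >= k),  X ~ Hypergeometric(N, K, n)

Bonferroni correction multiplies by the number of testable terms (terms with
K >= 1 in the background); adjusted p-values <= alpha flag enrichment.

Transcript-length bias (longer transcripts accumulate more reads and hence
more detections) is not modelled; when lengths are supplied and the study
and background mean lengths differ by more than 20% a warning is emitted so
the user can judge whether a length-aware test is warranted.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy.stats import hypergeom


def hypergeom_upper_tail(k, N: int, K: int, n: int):
    """P(X >= k) for X ~ Hypergeometric(N, K, n); ``k`` may be an array."""
    import numpy as np

    k_arr = np.asarray(k)
    if not (0 <= K <= N and 0 <= n <= N and (k_arr >= 0).all()):
        raise ValueError("require 0 <= K <= N, 0 <= n <= N, k >= 0")
    p = np.where(k_arr == 0, 1.0, hypergeom.sf(k_arr - 1, N, K, n))
    return float(p) if np.isscalar(k) else p


def hypergeometric_enrich(
    study,
    background,
    annot: dict,
    lengths: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-term enrichment of ``study`` against ``background``.

    Both sets are restricted to annotated transcripts; every term present in
    the background is tested (terms absent from the study get k=0, p=1).

    Raises
    ------
    ValueError
        listing offenders, if study is not a subset of background.
    """
    study, background = set(study), set(background)
    offenders = study - background
    if offenders:
        raise ValueError(
            f"study transcripts outside the background: {sorted(offenders)[:10]}")

    bg_annot = {t for t in background if annot.get(t)}
    st_annot = study & bg_annot
    if lengths is not None and len(st_annot) and len(bg_annot):
        mean_st = lengths.reindex(sorted(st_annot)).dropna().mean()
        mean_bg = lengths.reindex(sorted(bg_annot)).dropna().mean()
        if mean_bg > 0 and abs(mean_st - mean_bg) / mean_bg > 0.20:
            warnings.warn(
                "study and background mean transcript lengths differ by >20%; "
                "detection-probability length bias is not corrected here")

    term_bg: dict = {}
    term_st: dict = {}
    for t in bg_annot:
        for term in annot[t]:
            term_bg[term] = term_bg.get(term, 0) + 1
            if t in st_annot:
                term_st[term] = term_st.get(term, 0) + 1

    N, n = len(bg_annot), len(st_annot)
    rows = []
    for term in sorted(term_bg):
        K = term_bg[term]
        k = term_st.get(term, 0)
        rows.append((term, k, n, K, N, hypergeom_upper_tail(k, N, K, n)))
    return pd.DataFrame(rows, columns=["term_id", "k", "n", "K", "N", "p_raw"])


def bonferroni(results: pd.DataFrame, m: int | None = None,
               alpha: float = 0.05) -> pd.DataFrame:
    """Add p_adj = min(1, p_raw * m) and the enriched flag (p_adj <= alpha).

    ``m`` defaults to the number of testable terms in ``results`` (all rows,
    since only terms with K >= 1 are tabulated).
    """
    out = results.copy()
    if m is None:
        m = len(out)
    if m < 1:
        raise ValueError("m must be >= 1")
    out["p_adj"] = (out["p_raw"] * m).clip(upper=1.0)
    out["enriched"] = out["p_adj"] <= alpha
    return out.sort_values(["p_adj", "term_id"]).reset_index(drop=True)


def read_annotation(path) -> dict:
    """Read a two-column (transcript_id, term_id) TSV into an id -> terms map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    annot: dict = {}
    for t, term in df.itertuples(index=False):
        annot.setdefault(t, set()).add(term)
    return annot
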