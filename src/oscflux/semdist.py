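"""Semantic-distance scoring, median split, and inclusion filters.

Association responses are scored against word-embedding vectors: the
semantic distance between two words is 1 minus the cosine similarity of
their vectors, clamped to [0, 1] so that 0 means minimally and 1 maximally
different (a negative similarity clamps to 1 and is logged).  Within each
item the responses form an ordered series; the default ``consecutive`` mode
scores each response against its predecessor (the first response against the
cue), while ``forward_flow`` scores each response against the mean distance
to all previous words including the cue.

A per-participant, per-condition median split labels responses as lower or
higher semantic distance; ties at the median are assigned alternately
(starting with lower) so the two groups never differ by more than one
response.

Inclusion rules mirror a typical free-association EEG protocol and run in
order: epoch level (thinking time >= 1 s, <= 20% artefact-tagged samples),
participant level (>= 10 valid responses in total, >= 5 per condition), and
finally a group-level 3-standard-deviation outlier rule on the aggregated
dependent measures.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("oscflux.semdist")

MIN_THINKING_TIME = 1.0      # seconds
MAX_ARTEFACT_FRACTION = 0.20
MIN_TOTAL_RESPONSES = 10
MIN_RESPONSES_PER_CONDITION = 5
OUTLIER_SD = 3.0


def semantic_distance(v1: np.ndarray, v2: np.ndarray) -> float:
    """1 - cosine similarity, clamped to [0, 1]."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("vectors must have equal dimension")
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("zero vector has no direction; distance undefined")
    d = 1.0 - float(v1.dot(v2) / (n1 * n2))
    if d > 1.0:
        logger.info("negative similarity (raw distance %.4f) clamped to 1", d)
        return 1.0
    return max(d, 0.0)


def score_sequence(cue: str, responses: list[str], vectors: dict,
                   mode: str = "consecutive",
                   score_first_against_cue: bool = True) -> list[float]:
    """Distance series for one ordered response sequence.

    ``consecutive``: distance of response k to response k-1 (response 1 to
    the cue).  ``forward_flow``: mean distance of response k to all previous
    words including the cue.  Responses missing from the vector table are
    scored nan and logged (callers exclude them).  When
    ``score_first_against_cue`` is False the first response is scored nan.
    """
    if mode not in ("consecutive", "forward_flow"):
        raise ValueError("mode must be 'consecutive' or 'forward_flow'")
    if not responses:
        raise ValueError("empty response sequence")
    if cue not in vectors:
        raise KeyError(f"cue {cue!r} missing from vector table")
    history: list[np.ndarray] = [np.asarray(vectors[cue], float)]
    out: list[float] = []
    for k, word in enumerate(responses):
        if word not in vectors:
            logger.warning("word %r not in vector table; response excluded", word)
            out.append(float("nan"))
            continue
        v = np.asarray(vectors[word], float)
        if k == 0 and not score_first_against_cue:
            out.append(float("nan"))
        elif mode == "consecutive":
            out.append(semantic_distance(history[-1], v))
        else:
            out.append(float(np.mean([semantic_distance(h, v) for h in history])))
        history.append(v)
    return out


def score_table(responses: pd.DataFrame, vectors: dict,
                mode: str = "consecutive",
                score_first_against_cue: bool = True) -> pd.DataFrame:
    """Add a ``distance`` column to a response table.

    The table needs columns participant, item, condition, order, word; rows
    are scored item by item in response order.
    """
    df = responses.sort_values(["participant", "item", "order"]).copy()
    distances = np.full(len(df), np.nan)
    pos = 0
    for (_, item), grp in df.groupby(["participant", "item"], sort=False):
        series = score_sequence(item, grp["word"].tolist(), vectors, mode=mode,
                                score_first_against_cue=score_first_against_cue)
        distances[pos:pos + len(grp)] = series
        pos += len(grp)
    df["distance"] = distances
    return df


def median_split(distances: np.ndarray) -> np.ndarray:
    """Label distances 'lower' / 'higher' relative to their median.

    Values strictly below the median are lower, strictly above are higher;
    values equal to the median alternate starting with lower, so the final
    counts differ by at most one.  nan distances are labelled 'excluded'.
    Fewer than 2 scored values -> all 'excluded'.
    """
    distances = np.asarray(distances, dtype=float)
    labels = np.full(distances.shape, "excluded", dtype=object)
    scored = ~np.isnan(distances)
    if scored.sum() < 2:
        if scored.any():
            logger.warning("fewer than 2 scored responses; all excluded from split")
        return labels
    med = float(np.median(distances[scored]))
    labels[scored & (distances < med)] = "lower"
    labels[scored & (distances > med)] = "higher"
    tie_idx = np.flatnonzero(scored & (distances == med))
    n_lower = int(np.sum(labels == "lower"))
    n_higher = int(np.sum(labels == "higher"))
    next_label = "lower"
    for idx in tie_idx:
        # steer ties toward the smaller group; alternate from 'lower' on balance
        if n_lower < n_higher:
            lab = "lower"
        elif n_higher < n_lower:
            lab = "higher"
        else:
            lab = next_label
            next_label = "higher" if lab == "lower" else "lower"
        labels[idx] = lab
        if lab == "lower":
            n_lower += 1
        else:
            n_higher += 1
    return labels


def split_table(scored: pd.DataFrame) -> pd.DataFrame:
    """Apply the median split per participant x condition; adds ``split``."""
    df = scored.copy()
    df["split"] = "excluded"
    for _, grp in df.groupby(["participant", "condition"], sort=False):
        df.loc[grp.index, "split"] = median_split(grp["distance"].to_numpy())
    return df


def apply_inclusion_filters(records: pd.DataFrame,
                            measures: pd.DataFrame | None = None,
                            artefact_fraction: pd.Series | None = None):
    """Apply the epoch-, participant- and group-level inclusion rules.

    Parameters
    ----------
    records
        Response table with participant, condition, thinking_time (one row
        per epoch), optionally an ``artefact_fraction`` column.
    measures
        Optional aggregated dependent measures (one row per participant,
        numeric columns) for the group-level 3-SD extreme-outlier rule; a
        participant outlying on any measure is removed entirely.
    artefact_fraction
        Optional per-row artefact fraction overriding the column.

    Returns
    -------
    (kept_records, report)
        The surviving rows and a per-rule exclusion-count report.
    """
    df = records.copy()
    if artefact_fraction is not None:
        df["artefact_fraction"] = np.asarray(artefact_fraction, float)
    if "artefact_fraction" not in df.columns:
        df["artefact_fraction"] = 0.0
    report: dict[str, int] = {}

    short = df["thinking_time"] < MIN_THINKING_TIME
    report["epoch_thinking_time_lt_1s"] = int(short.sum())
    arty = df["artefact_fraction"] > MAX_ARTEFACT_FRACTION
    report["epoch_artefact_gt_20pct"] = int((arty & ~short).sum())
    df = df[~short & ~arty]

    totals = df.groupby("participant").size()
    per_cond = df.groupby(["participant", "condition"]).size().unstack(fill_value=0)
    bad_total = set(totals[totals < MIN_TOTAL_RESPONSES].index)
    bad_total |= set(records["participant"].unique()) - set(totals.index)
    bad_cond = set(per_cond[(per_cond < MIN_RESPONSES_PER_CONDITION).any(axis=1)].index)
    report["participant_lt_10_responses"] = len(bad_total)
    report["participant_lt_5_per_condition"] = len(bad_cond - bad_total)
    df = df[~df["participant"].isin(bad_total | bad_cond)]

    outliers: set = set()
    if measures is not None and len(measures) > 0:
        m = measures.set_index("participant") if "participant" in measures.columns \
            else measures
        m = m.loc[m.index.intersection(df["participant"].unique())]
        num = m.select_dtypes(include=[np.number])
        for col in num.columns:
            vals = num[col].dropna()
            if len(vals) < 3 or vals.std(ddof=1) == 0:
                continue
            z = (vals - vals.mean()) / vals.std(ddof=1)
            outliers |= set(vals.index[np.abs(z) > OUTLIER_SD])
        df = df[~df["participant"].isin(outliers)]
    report["participant_outlier_3sd"] = len(outliers)
    report["n_kept_epochs"] = int(len(df))
    report["n_kept_participants"] = int(df["participant"].nunique())
    return df, report
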