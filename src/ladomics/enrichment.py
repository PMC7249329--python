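"""Observed/expected enrichment statistics for feature sets in tracks.

The central quantity is a signed fold enrichment of a *selection* (e.g.
differentially methylated probes) within a *track* (e.g. lamin A LADs),
measured against expectation under independence:

    expected    = n_selected * (n_universe_in_track / n_universe)
    signed_fold = observed / expected          (observed >= expected)
                = -expected / observed         (depletion)

so a depletion prints as a negative ratio (e.g. -1.56-fold) and exact
agreement with expectation as +1.0.  Significance is assessed by
Pearson's chi-squared on the implied 2x2 table with Yates' continuity
correction (capped so the independence case gives exactly chi2 = 0), or
by Fisher's exact test.

Stratified delta-beta comparisons (LAD / solo-WCGW PMD / HMD / histone
marks) report the per-stratum median case-minus-control difference with
an unpaired Welch t-test of the per-probe group means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import BetaMatrix, welch_t
from .intervals import AnnotationTrack, overlaps_any

__all__ = [
    "EnrichmentResult",
    "fold_enrichment",
    "fisher_enrichment",
    "peak_feature_distribution",
    "stratified_delta_beta",
    "yates_chi2",
    "probe_track_membership",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Signed fold enrichment of one selection in one track."""

    track_name: str
    n_universe: int
    n_universe_in_track: int
    n_selected: int
    observed: int
    expected: float
    signed_fold: float
    test_name: str
    statistic: float
    p_value: float

    @property
    def fold(self) -> float:
        """Plain observed/expected ratio (mathematically regular column)."""
        return self.observed / self.expected


def yates_chi2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared with Yates continuity correction on a 2x2 table.

    The correction term subtracted from each |O - E| is capped at
    |O - E| itself (min(0.5, |O - E|)), so it never over-corrects past
    zero and an exactly independent table yields chi2 = 0, p = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    rows = t.sum(axis=1, keepdims=True)
    cols = t.sum(axis=0, keepdims=True)
    total = t.sum()
    if total == 0 or np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("degenerate margin in 2x2 table")
    expected = rows @ cols / total
    diff = np.abs(t - expected)
    corrected = diff - np.minimum(0.5, diff)
    chi2 = float(np.sum(corrected**2 / expected))
    return chi2, float(stats.chi2.sf(chi2, 1))


def fold_enrichment(
    selected: np.ndarray,
    in_track: np.ndarray,
    track_name: str = "",
) -> EnrichmentResult:
    """Signed fold enrichment of a boolean selection within a boolean
    track membership, over one shared universe of features."""
    selected = np.asarray(selected, dtype=bool)
    in_track = np.asarray(in_track, dtype=bool)
    if selected.shape != in_track.shape:
        raise ValueError("selection and track-membership vectors are misaligned")
    n_universe = selected.size
    n_in = int(in_track.sum())
    n_sel = int(selected.sum())
    if n_sel == 0:
        raise ValueError("empty selection")
    if n_in == 0 or n_in == n_universe:
        raise ValueError("degenerate track margin (no probes in/out of track)")
    observed = int((selected & in_track).sum())
    expected = n_sel * n_in / n_universe
    if observed >= expected:
        signed = observed / expected
    else:
        signed = -expected / observed if observed > 0 else -np.inf
    table = np.array(
        [
            [observed, n_sel - observed],
            [n_in - observed, n_universe - n_sel - n_in + observed],
        ]
    )
    chi2, p = yates_chi2(table)
    return EnrichmentResult(
        track_name=track_name,
        n_universe=n_universe,
        n_universe_in_track=n_in,
        n_selected=n_sel,
        observed=observed,
        expected=expected,
        signed_fold=float(signed),
        test_name="yates_chi2",
        statistic=chi2,
        p_value=p,
    )


def fisher_enrichment(table: np.ndarray) -> dict[str, float]:
    """Fisher's exact test on a 2x2 table.

    Two-sided p sums hypergeometric probabilities no larger than that of
    the observed table (fixed margins).  The reported odds ratio is the
    sample odds ratio ``ad/bc`` (inf or 0 for a zero off-/on-diagonal
    cell, with the p-value still finite).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("degenerate margin in 2x2 table")
    a, b, c, d = t.ravel()
    if b * c == 0:
        odds = np.inf if a * d > 0 else (0.0 if a == 0 or d == 0 else np.nan)
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return {"odds_ratio": float(odds), "p_two_sided": float(p)}


def peak_feature_distribution(
    peaks: AnnotationTrack,
    feature_tracks: Mapping[str, AnnotationTrack],
    lad_track_names: Sequence[str] = (),
) -> pd.DataFrame:
    """Distribution of peaks across (non-exclusive) feature categories.

    A peak counts toward every track it overlaps by >= 1 bp.  When
    ``lad_track_names`` is given, an extra ``non_LAD`` row counts peaks
    overlapping none of those tracks.
    """
    if len(peaks) == 0:
        raise ValueError("empty peak track")
    peak_list = list(peaks)
    total = len(peak_list)
    rows = {}
    flags = {}
    for name, track in feature_tracks.items():
        hit = overlaps_any(peak_list, track)
        flags[name] = hit
        rows[name] = int(hit.sum())
    if lad_track_names:
        missing = [n for n in lad_track_names if n not in feature_tracks]
        if missing:
            raise ValueError(f"unknown LAD track names: {missing}")
        any_lad = np.zeros(total, dtype=bool)
        for n in lad_track_names:
            any_lad |= flags[n]
        rows["non_LAD"] = int((~any_lad).sum())
    out = pd.DataFrame({"count": pd.Series(rows)})
    out["fraction"] = out["count"] / total
    out.index.name = "feature"
    return out


def probe_track_membership(
    annot: pd.DataFrame, tracks: Mapping[str, AnnotationTrack]
) -> pd.DataFrame:
    """Boolean probe x track membership from 1-based probe coordinates.

    Computed once from the probe annotation (half-open point overlap) and
    reused by every stratified figure so the strata stay consistent.
    """
    out = {}
    chroms = annot["chrom"].to_numpy()
    pos = annot["pos"].to_numpy(dtype=np.int64)
    for name, track in tracks.items():
        out[name] = np.array(
            [track.overlaps(c, p - 1, p) for c, p in zip(chroms, pos)], dtype=bool
        )
    return pd.DataFrame(out, index=annot.index)


def stratified_delta_beta(
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    strata: Mapping[str, np.ndarray],
    paired: bool = False,
) -> pd.DataFrame:
    """Per-stratum methylation difference between case and control.

    For each probe the case and control group means are computed; within
    each stratum the median ``delta_beta`` (case - control) is reported
    together with a Welch t-test comparing the per-probe case means
    against the per-probe control means (unpaired by default; ``paired``
    tests the per-probe differences against zero).
    """
    groups = sheet.loc[beta.sample_ids, "group"].to_numpy()
    case = groups == "case"
    if case.sum() < 1 or (~case).sum() < 1:
        raise ValueError("both groups required")
    vals = beta.values.to_numpy()
    mean_case = vals[:, case].mean(axis=1)
    mean_control = vals[:, ~case].mean(axis=1)
    delta = mean_case - mean_control

    records = []
    for name, mask in strata.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.size != len(beta.probe_ids):
            raise ValueError(f"stratum {name!r} mask misaligned with probes")
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"stratum {name!r} is empty")
        if n < 2:
            raise ValueError(f"stratum {name!r} has a single probe; cannot test")
        if paired:
            res = stats.ttest_rel(mean_case[mask], mean_control[mask])
            t, df, p = float(res.statistic), float(n - 1), float(res.pvalue)
        else:
            w = welch_t(mean_case[mask], mean_control[mask])
            t, df, p = w["t"], w["df"], w["p"]
        records.append(
            {
                "stratum": name,
                "n_probes": n,
                "median_delta_beta": float(np.median(delta[mask])),
                "t": t,
                "df": df,
                "p": p,
            }
        )
    return pd.DataFrame.from_records(records).set_index("stratum")
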