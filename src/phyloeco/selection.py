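"""Unsupervised recursive decorrelation of features.

The reduction keeps original features (no PCA-style transforms): while
any pair of remaining features is correlated beyond a user threshold in
absolute value, the most correlated pair is located and the member that
is more redundant with the *rest* of the features — the one whose
strongest absolute correlation to a third remaining feature is larger —
is discarded.  The surviving subset is pairwise weakly correlated, and
an audit trail records every discard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class SelectionError(ValueError):
    """Raised on inputs the selection cannot operate on."""


@dataclass(frozen=True)
class SelectionStep:
    """One discard: which feature was dropped, against which partner."""

    discarded: str
    kept_partner: str
    pair_correlation: float
    #: The discarded feature's strongest (signed) correlation to a third
    #: remaining feature at the time of discard; None when no third
    #: feature remained.
    discard_reason_correlation: float | None


@dataclass(frozen=True)
class SelectionAudit:
    """Full record of a decorrelation run."""

    steps: tuple[SelectionStep, ...]
    final_subset: tuple[str, ...]
    threshold: float
    discarded: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "discarded", tuple(s.discarded for s in self.steps))

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "final_subset": list(self.final_subset),
            "steps": [
                {
                    "discarded": s.discarded,
                    "kept_partner": s.kept_partner,
                    "pair_correlation": s.pair_correlation,
                    "discard_reason_correlation": s.discard_reason_correlation,
                }
                for s in self.steps
            ],
        }


def feature_correlation_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between feature columns.

    Requires at least three rows (species) and no constant column;
    constant columns are rejected with their ids listed so data problems
    surface instead of propagating NaNs.
    """
    if m.shape[0] < 3:
        raise SelectionError("need at least 3 species to correlate features")
    values = m.to_numpy(dtype=float)
    constant = m.columns[values.std(axis=0) == 0.0].tolist()
    if constant:
        raise SelectionError(f"constant feature column(s): {constant}")
    corr = np.corrcoef(values, rowvar=False)
    corr = (corr + corr.T) / 2.0  # enforce bit-exact symmetry
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=m.columns, columns=m.columns)


def _pick_discard(
    a: str, b: str, corr: pd.DataFrame, remaining: list[str]
) -> tuple[str, str, float | None]:
    """Decide which of a correlated pair to discard.

    Primary rule: discard the member with the larger maximal absolute
    correlation to any third remaining feature.  Ties fall back to the
    larger mean absolute correlation to all other remaining features,
    then to the lexicographically larger feature_id.
    Returns (discarded, kept, signed correlation behind the decision).
    """
    others = [f for f in remaining if f not in (a, b)]

    def third_party(x: str) -> tuple[float, float | None]:
        if not others:
            return (-np.inf, None)
        sub = corr.loc[x, others]
        k = sub.abs().to_numpy().argmax()
        return (abs(sub.iloc[k]), float(sub.iloc[k]))

    def mean_abs(x: str) -> float:
        rest = [f for f in remaining if f != x]
        return float(corr.loc[x, rest].abs().mean()) if rest else 0.0

    ta, ra = third_party(a)
    tb, rb = third_party(b)
    if ta > tb:
        return a, b, ra
    if tb > ta:
        return b, a, rb
    ma, mb = mean_abs(a), mean_abs(b)
    if ma > mb:
        return a, b, ra
    if mb > ma:
        return b, a, rb
    return (a, b, ra) if a > b else (b, a, rb)


def select_uncorrelated(m: pd.DataFrame, threshold: float = 0.5) -> SelectionAudit:
    """Reduce a feature matrix to a pairwise weakly-correlated subset.

    While any pair of remaining features has ``|r| > threshold`` (strict:
    a pair at exactly the threshold survives), the pair with maximal
    ``|r|`` is taken and one member discarded (see :func:`_pick_discard`).
    Pairwise correlations do not change when other columns are removed,
    so the loop runs on one static correlation matrix.  Ties between
    pairs at the same ``|r|`` are broken by lexicographic pair order.

    The postcondition — the final subset has maximal off-diagonal
    ``|r| <= threshold`` — is asserted on every run.
    """
    if m.shape[1] < 2:
        raise SelectionError("need at least 2 features")
    corr = feature_correlation_matrix(m)
    remaining = list(m.columns)
    steps: list[SelectionStep] = []
    while len(remaining) >= 2:
        sub = corr.loc[remaining, remaining].to_numpy()
        acorr = np.triu(np.abs(sub), k=1)
        best = acorr.max()
        if best <= threshold:
            break
        pairs = sorted(
            (remaining[i], remaining[j]) for i, j in zip(*np.nonzero(acorr == best))
        )
        a, b = pairs[0]
        discarded, kept, reason = _pick_discard(a, b, corr, remaining)
        steps.append(
            SelectionStep(
                discarded=discarded,
                kept_partner=kept,
                pair_correlation=float(corr.loc[a, b]),
                discard_reason_correlation=reason,
            )
        )
        remaining.remove(discarded)

    final = corr.loc[remaining, remaining].to_numpy()
    off = np.abs(final - np.eye(len(remaining)))
    assert off.max(initial=0.0) <= threshold + 1e-12, "decorrelation postcondition violated"
    return SelectionAudit(tuple(steps), tuple(remaining), threshold)
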