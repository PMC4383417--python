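"""Statistical procedures for the rating studies.

Four analysis families operate on long-format rating tables (pandas
DataFrames):

* second-level residual regression — per participant, ratings and the image
  property are both residualized on the chronological age of the faces; the
  per-participant OLS coefficient of the property residual is then tested
  against zero with a one-sample t-test across participants.  By the
  Frisch-Waugh-Lovell theorem the per-participant coefficient equals the
  partial coefficient of the property in a joint regression of rating on
  (age, property).
* one-way repeated-measures ANOVA with Greenhouse-Geisser correction and an
  orthogonal-polynomial quadratic contrast — for ordered mask/background
  slope conditions (a dip or peak at the middle slope shows up as a
  significant quadratic trend).
* two-alternative forced-choice tallies — absolute and pairing-conditional
  selection percentages plus per-participant paired t-tests between the two
  pairing contexts of each category.
* rank tests — Friedman across conditions, with pairwise Wilcoxon
  signed-rank (tie-corrected normal approximation) and sign tests (exact
  binomial up to n = 25).

Expected table columns are documented per function; ratings are stored on
the inverted scale (higher = more attractive) throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TermTest",
    "SecondLevelResult",
    "TrendResult",
    "ChoiceTally",
    "RankTestResult",
    "residualize",
    "second_level_regression",
    "rm_anova_quadratic",
    "quadratic_weights",
    "gg_epsilon",
    "choice_tally",
    "rank_tests",
    "pearson_with_p",
]


# --------------------------------------------------------------------------
# results


@dataclass
class TermTest:
    """One-sample t-test over per-participant coefficients of one term."""

    t: float
    df: int
    p: float
    mean_beta: float
    beta_min: float
    beta_max: float


@dataclass
class SecondLevelResult:
    """Per-participant coefficients and their group-level t-tests.

    ``betas`` is a participant x term DataFrame; ``tests`` maps each term
    ('property', and with gender also 'gender' and 'interaction') to its
    :class:`TermTest`.  df is always n_participants - 1.
    """

    property_name: str
    betas: pd.DataFrame
    tests: dict[str, TermTest]

    @property
    def property_test(self) -> TermTest:
        return self.tests["property"]


@dataclass
class TrendResult:
    """One-way repeated-measures ANOVA with GG correction and the quadratic
    orthogonal-polynomial contrast (contrast F = contrast t squared,
    df (1, n-1))."""

    f: float
    df_num: int
    df_den: int
    gg_epsilon: float
    p_uncorrected: float
    p_gg: float
    quad_f: float
    quad_t: float
    quad_df: int
    quad_p: float
    condition_means: pd.Series = field(repr=False)


@dataclass
class ChoiceTally:
    """Forced-choice selection tallies.

    ``counts``/``percent``: absolute selections per category and their share
    of all trials (the three percentages sum to 100).  ``conditional``:
    conditional.loc[A, B] = % of A-vs-B trials in which A was chosen
    (conditional.loc[A, B] + conditional.loc[B, A] = 100).
    ``pairing_tests``: per category, the paired t-test across participants
    between its selection rates in its two pairing contexts.
    """

    counts: pd.Series
    percent: pd.Series
    conditional: pd.DataFrame
    pairing_tests: dict[str, TermTest]
    per_participant: pd.DataFrame = field(repr=False)


@dataclass
class RankTestResult:
    """Friedman test plus pairwise Wilcoxon signed-rank and sign tests."""

    friedman_chi2: float
    df: int
    p: float
    wilcoxon: pd.DataFrame
    sign: pd.DataFrame


# --------------------------------------------------------------------------
# building blocks


def residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residuals of the OLS regression of centered y on centered x.

    Residuals sum to zero; if x and y are uncorrelated they equal centered y.
    """
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if y.shape != x.shape or y.ndim != 1 or len(y) < 3:
        raise ValueError("y and x must be equal-length 1-D vectors of length >= 3")
    xc = x - x.mean()
    sxx = xc @ xc
    if sxx == 0:
        raise ValueError("x is constant; cannot residualize on it")
    yc = y - y.mean()
    return yc - (xc @ yc / sxx) * xc


def _one_sample_t(betas: np.ndarray) -> TermTest:
    res = stats.ttest_1samp(betas, 0.0)
    return TermTest(
        t=float(res.statistic),
        df=len(betas) - 1,
        p=float(res.pvalue),
        mean_beta=float(betas.mean()),
        beta_min=float(betas.min()),
        beta_max=float(betas.max()),
    )


def second_level_regression(
    table: pd.DataFrame,
    prop: str,
    with_gender: bool = False,
    max_missing: float = 0.4,
) -> SecondLevelResult:
    """Two-stage residual regression of ratings on an image property.

    ``table`` needs columns participant_id, stimulus_id, rating, face_age,
    and ``prop`` (and face_gender when ``with_gender``).  The property is
    residualized on face age once at the image level; per participant the
    ratings are residualized on face age and regressed on the property
    residuals (plus effect-coded gender, female = +1 / male = -1, and the
    property x gender interaction when requested).  A one-sample t-test over
    the per-participant coefficients gives the group-level result.

    Participants missing more than ``max_missing`` of the stimuli are
    dropped; remaining missing rows are dropped listwise per participant with
    a warning.
    """
    required = {"participant_id", "stimulus_id", "rating", "face_age", prop}
    if with_gender:
        required.add("face_gender")
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"rating table lacks columns {sorted(missing_cols)}")

    stim = table.drop_duplicates("stimulus_id").set_index("stimulus_id")
    prop_resid = pd.Series(
        residualize(stim[prop].to_numpy(), stim["face_age"].to_numpy()),
        index=stim.index,
    )
    if np.allclose(prop_resid, 0):
        raise ValueError(f"property {prop!r} is constant after residualization on age")
    if with_gender:
        g = stim["face_gender"].map({"F": 1.0, "M": -1.0})
        if g.isna().any():
            raise ValueError("face_gender must be 'F' or 'M'")

    n_stimuli = len(stim)
    rows: list[dict] = []
    terms = ["property"] + (["gender", "interaction"] if with_gender else [])
    for pid, sub in table.groupby("participant_id", sort=True):
        sub = sub.dropna(subset=["rating"])
        if len(sub) < (1 - max_missing) * n_stimuli:
            warnings.warn(f"participant {pid!r} dropped: "
                          f"only {len(sub)}/{n_stimuli} stimuli rated")
            continue
        if len(sub) < n_stimuli:
            warnings.warn(f"participant {pid!r}: {n_stimuli - len(sub)} missing "
                          "rows dropped listwise")
        ages = sub["face_age"].to_numpy()
        y = residualize(sub["rating"].to_numpy(), ages)
        pr = prop_resid.loc[sub["stimulus_id"]].to_numpy()
        cols = [pr]
        if with_gender:
            gv = g.loc[sub["stimulus_id"]].to_numpy()
            cols += [gv, pr * gv]
        x = np.column_stack([np.ones(len(y))] + cols)
        beta = np.linalg.lstsq(x, y, rcond=None)[0]
        rows.append({"participant_id": pid,
                     **{term: beta[i + 1] for i, term in enumerate(terms)}})
    if len(rows) < 3:
        raise ValueError(f"need at least 3 complete participants, have {len(rows)}")
    betas = pd.DataFrame(rows).set_index("participant_id")
    tests = {term: _one_sample_t(betas[term].to_numpy()) for term in terms}
    return SecondLevelResult(prop, betas, tests)


def quadratic_weights(k: int) -> np.ndarray:
    """Orthogonal-polynomial quadratic contrast weights for k equally spaced
    levels (integer-scaled, e.g. (2, -1, -2, -1, 2) for k = 5)."""
    x = np.arange(k, dtype=np.float64)
    x -= x.mean()
    w = x**2
    w -= w.mean()
    # orthogonalize against the linear trend (already orthogonal for
    # equally spaced levels, kept for safety)
    w -= (w @ x) / (x @ x) * x
    scale = np.min(np.abs(w[w != 0]))
    w = w / scale
    if np.allclose(w, np.rint(w)):
        w = np.rint(w)
    return w


def gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity correction factor.

    Computed from the doubly centered sample covariance matrix of the
    n x k condition scores; always in [1/(k-1), 1], and exactly 1 for k = 2
    (a single difference score cannot violate sphericity).
    """
    data = np.asarray(data, dtype=np.float64)
    n, k = data.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 conditions and 2 participants")
    s = np.cov(data, rowvar=False, ddof=1)
    c = np.eye(k) - np.full((k, k), 1.0 / k)
    m = c @ s @ c
    tr = np.trace(m)
    denom = (k - 1) * np.sum(m * m.T)
    eps = 1.0 if denom == 0 else float(tr**2 / denom)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova_quadratic(
    table: pd.DataFrame,
    condition_order: list[str],
    value: str = "rating",
) -> TrendResult:
    """One-way within-subject ANOVA over ordered conditions plus the
    quadratic trend contrast.

    ``table`` needs columns participant_id, condition and ``value``; cell
    means per participant x condition are formed first (a participant may
    rate many stimuli per condition).  Missing cells raise — no imputation.
    The omnibus F is MS(condition) / MS(participant x condition);
    Greenhouse-Geisser epsilon is computed from the sample covariance of the
    condition scores and applied to both df.  The quadratic contrast is a
    one-sample t-test of the per-participant contrast scores; its F (= t^2)
    has df (1, n-1).
    """
    for col in ("participant_id", "condition", value):
        if col not in table.columns:
            raise ValueError(f"rating table lacks column {col!r}")
    cell = (
        table.groupby(["participant_id", "condition"], sort=True,
                      observed=True)[value]
        .mean()
        .unstack("condition")
    )
    missing = [c for c in condition_order if c not in cell.columns]
    if missing:
        raise ValueError(f"conditions absent from table: {missing}")
    cell = cell[condition_order]
    if cell.isna().any().any():
        raise ValueError("missing participant x condition cells; no imputation")
    data = cell.to_numpy()
    n, k = data.shape
    if k < 3:
        raise ValueError("need at least 3 conditions for a trend analysis")

    grand = data.mean()
    cond_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df_num, df_den = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df_num
    ms_err = ss_err / df_den
    f_stat = ms_cond / ms_err if ms_err > 0 else np.inf if ss_cond > 0 else 0.0

    eps = gg_epsilon(data)

    p_unc = float(stats.f.sf(f_stat, df_num, df_den)) if np.isfinite(f_stat) else 0.0
    p_gg = (
        float(stats.f.sf(f_stat, eps * df_num, eps * df_den))
        if np.isfinite(f_stat)
        else 0.0
    )

    w = quadratic_weights(k)
    scores = data @ w
    tt = stats.ttest_1samp(scores, 0.0)
    quad_t = float(tt.statistic)
    return TrendResult(
        f=float(f_stat),
        df_num=df_num,
        df_den=df_den,
        gg_epsilon=eps,
        p_uncorrected=p_unc,
        p_gg=p_gg,
        quad_f=quad_t**2,
        quad_t=quad_t,
        quad_df=n - 1,
        quad_p=float(tt.pvalue),
        condition_means=pd.Series(cond_means, index=condition_order),
    )


def choice_tally(trials: pd.DataFrame) -> ChoiceTally:
    """Tally a two-alternative forced-choice table.

    ``trials`` needs columns participant_id, category_left, category_right
    and chosen_side ('left' or 'right'); the two categories of a trial must
    differ.  Exactly three categories are expected (e.g. steep / original /
    shallow), giving each category two pairing contexts.
    """
    for col in ("participant_id", "category_left", "category_right", "chosen_side"):
        if col not in trials.columns:
            raise ValueError(f"trial table lacks column {col!r}")
    cats = sorted(set(trials["category_left"]) | set(trials["category_right"]))
    if (trials["category_left"] == trials["category_right"]).any():
        raise ValueError("same-category pairings are not allowed")
    bad = set(trials["chosen_side"]) - {"left", "right"}
    if bad:
        raise ValueError(f"chosen_side must be 'left' or 'right', got {sorted(bad)}")

    t = trials.copy()
    left = t["chosen_side"] == "left"
    t["chosen"] = np.where(left, t["category_left"], t["category_right"])
    t["opponent"] = np.where(left, t["category_right"], t["category_left"])

    n_trials = len(t)
    counts = t["chosen"].value_counts().reindex(cats, fill_value=0)
    percent = counts / n_trials * 100.0

    conditional = pd.DataFrame(np.nan, index=cats, columns=cats)
    per_part_rows = []
    for a, b in combinations(cats, 2):
        pair = t[((t["category_left"] == a) & (t["category_right"] == b))
                 | ((t["category_left"] == b) & (t["category_right"] == a))]
        if len(pair):
            pct_a = (pair["chosen"] == a).mean() * 100.0
            conditional.loc[a, b] = pct_a
            conditional.loc[b, a] = 100.0 - pct_a
        grp = pair.groupby("participant_id")["chosen"]
        frac = grp.apply(lambda s, cat=a: (s == cat).mean() * 100.0)
        for pid, v in frac.items():
            per_part_rows.append(
                {"participant_id": pid, "category": a, "opponent": b, "percent": v}
            )
            per_part_rows.append(
                {"participant_id": pid, "category": b, "opponent": a,
                 "percent": 100.0 - v}
            )
    per_participant = pd.DataFrame(per_part_rows)

    pairing_tests: dict[str, TermTest] = {}
    for cat in cats:
        opponents = [c for c in cats if c != cat]
        if len(opponents) != 2:
            continue
        wide = (
            per_participant[per_participant["category"] == cat]
            .pivot(index="participant_id", columns="opponent", values="percent")
            .dropna()
        )
        if len(wide) >= 2 and wide.shape[1] == 2:
            diffs = wide[opponents[0]].to_numpy() - wide[opponents[1]].to_numpy()
            pairing_tests[cat] = _one_sample_t(diffs)
    return ChoiceTally(counts, percent, conditional, pairing_tests, per_participant)


def rank_tests(matrix: pd.DataFrame) -> RankTestResult:
    """Friedman test across conditions plus pairwise Wilcoxon and sign tests.

    ``matrix`` is a complete participants x conditions table of scores.
    Friedman ranks within participants (average ranks for ties); Wilcoxon
    uses the tie-corrected normal approximation; the sign test is exact
    binomial for n <= 25 non-tied pairs and a continuity-corrected normal
    approximation beyond.
    """
    if matrix.isna().any().any():
        raise ValueError("missing cells; rank tests need a complete matrix")
    data = matrix.to_numpy(dtype=np.float64)
    n, k = data.shape
    if n < 5:
        warnings.warn("fewer than 5 participants: normal approximations unreliable")
    if np.all(np.ptp(data, axis=1) == 0):
        # every participant's scores fully tied: ranks carry no information
        chi2, p = 0.0, 1.0
    else:
        chi2, p = stats.friedmanchisquare(*(data[:, j] for j in range(k)))

    cols = list(matrix.columns)
    wil = pd.DataFrame(np.nan, index=cols, columns=cols)
    wil_p = pd.DataFrame(np.nan, index=cols, columns=cols)
    sgn = pd.DataFrame(np.nan, index=cols, columns=cols)
    sgn_p = pd.DataFrame(np.nan, index=cols, columns=cols)
    for a, b in combinations(range(k), 2):
        d = data[:, a] - data[:, b]
        nz = d[d != 0]
        if len(nz):
            res = stats.wilcoxon(d, zero_method="wilcox", correction=False,
                                 method="approx")
            z = float(res.zstatistic)
            wp = float(res.pvalue)
        else:
            z, wp = 0.0, 1.0
        wil.iloc[a, b] = wil.iloc[b, a] = z
        wil_p.iloc[a, b] = wil_p.iloc[b, a] = wp

        n_eff = len(nz)
        pos = int(np.sum(nz > 0))
        if n_eff == 0:
            zs, sp = 0.0, 1.0
        elif n_eff <= 25:
            sp = float(stats.binomtest(pos, n_eff, 0.5).pvalue)
            zs = float(pos - n_eff / 2)
        else:
            zs = (pos - n_eff / 2 - 0.5 * np.sign(pos - n_eff / 2)) / np.sqrt(n_eff / 4)
            sp = float(2 * stats.norm.sf(abs(zs)))
        sgn.iloc[a, b] = sgn.iloc[b, a] = zs
        sgn_p.iloc[a, b] = sgn_p.iloc[b, a] = sp

    wilcoxon = pd.concat({"z": wil, "p": wil_p}, axis=1)
    sign = pd.concat({"statistic": sgn, "p": sgn_p}, axis=1)
    return RankTestResult(float(chi2), k - 1, float(p), wilcoxon, sign)


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
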