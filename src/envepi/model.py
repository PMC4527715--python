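"""Per-feature factorial modeling of log2 fold changes under two stimuli.

Each feature's replicate fold changes in the three test conditions (stimulus
A alone, stimulus B alone, both concurrently) are fit with a cell-means
linear model: one coefficient per condition and no intercept, since the
baseline fold change is identically zero by construction. This is the
saturated main-effects + interaction parameterization of the 2x2 design
refit to condition means, so the three "effect size estimates" are the
condition mean fold changes — the quantities the downstream interaction
classification thresholds and signs.

For feature i with condition means beta_c, replicate counts n_c and pooled
residual variance s^2 = SS_within / (n - 3):

    se_c    = s / sqrt(n_c)
    t_c     = beta_c / se_c                       (df = n - 3)
    F       = [sum_c n_c beta_c^2 / 3] / s^2      (3, n - 3) df

The overall F tests all three condition means jointly zero; its p-values are
Benjamini-Hochberg adjusted across features, and a feature is a responder
when its adjusted p (q) is <= the FDR threshold. Coefficient p-values are
used raw for the per-stimulus differential-expression calls.

Usage::

    model = StimulusResponseModel(matrix)          # a FoldChangeMatrix
    res = model.fit()                              # -> StimulusResponseResults
    res.summary()
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import (
    EpistasisResult,
    InteractionCall,
    InteractionClass,
    calls_to_frame,
    classify_interaction,
    epistasis_test,
    epistasis_to_frame,
    summarize_classes,
)
from .exceptions import ConfigError, InsufficientReplicationError
from .io import CONDITION_LABELS, FoldChangeMatrix


@dataclass
class FeatureModelFit:
    """Cell-means fit for a single feature (conditions ordered A, B, AB)."""

    feature_id: str
    beta: np.ndarray
    se: np.ndarray
    coef_p: np.ndarray
    df_resid: int
    anova_F: float
    anova_p: float
    zero_variance: bool = False
    q: float = np.nan

    @property
    def direction(self) -> np.ndarray:
        return np.sign(self.beta).astype(int)


def fit_feature_model(
    values_by_condition: dict[str, np.ndarray], feature_id: str = ""
) -> FeatureModelFit:
    """Fit the cell-means model to one feature's replicate fold changes.

    ``values_by_condition`` maps "A"/"B"/"AB" to replicate arrays; each
    condition needs >= 2 replicates. Zero residual variance (noiseless
    input) is handled by convention: coefficient p = 0 where beta != 0 and
    1 where beta = 0, flagged via ``zero_variance``.
    """
    groups = []
    for label in CONDITION_LABELS:
        if label not in values_by_condition:
            raise InsufficientReplicationError(f"condition {label} missing")
        g = np.asarray(values_by_condition[label], float)
        if g.size < 2:
            raise InsufficientReplicationError(
                f"condition {label} has {g.size} replicates (needs >= 2)"
            )
        groups.append(g)
    n_c = np.array([g.size for g in groups])
    n = int(n_c.sum())
    df_resid = n - 3
    beta = np.array([g.mean() for g in groups])
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    s2 = ss_within / df_resid
    if s2 <= 0.0:
        coef_p = np.where(beta != 0.0, 0.0, 1.0)
        anova_p = 0.0 if np.any(beta != 0.0) else 1.0
        return FeatureModelFit(
            feature_id=feature_id,
            beta=beta,
            se=np.zeros(3),
            coef_p=coef_p,
            df_resid=df_resid,
            anova_F=np.inf if np.any(beta != 0.0) else 0.0,
            anova_p=anova_p,
            zero_variance=True,
        )
    se = np.sqrt(s2 / n_c)
    t = beta / se
    coef_p = 2.0 * stats.t.sf(np.abs(t), df_resid)
    F = float((n_c * beta**2).sum() / 3.0 / s2)
    anova_p = float(stats.f.sf(F, 3, df_resid))
    return FeatureModelFit(
        feature_id=feature_id,
        beta=beta,
        se=se,
        coef_p=coef_p,
        df_resid=df_resid,
        anova_F=F,
        anova_p=anova_p,
    )


def adjust_fdr_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ConfigError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_responders(
    q: np.ndarray, q_threshold: float = 0.05
) -> tuple[np.ndarray, dict]:
    """Responder iff BH-adjusted overall p (q) <= threshold."""
    q = np.asarray(q, float)
    if np.any(np.isnan(q)):
        raise ConfigError("q-values missing; apply BH across all features first")
    responder = q <= q_threshold
    counts = {
        "responders": int(responder.sum()),
        "non_responders": int((~responder).sum()),
    }
    return responder, counts


def stimulus_de_calls(
    coef_p: np.ndarray, responder: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, dict]:
    """Per-condition differential-expression calls.

    A feature is DE in a condition iff it is a responder and that
    condition's coefficient p-value is < alpha (strict).
    """
    coef_p = np.asarray(coef_p, float)
    responder = np.asarray(responder, bool)
    de = (coef_p < alpha) & responder[:, None]
    totals = {
        label: int(de[:, k].sum()) for k, label in enumerate(CONDITION_LABELS)
    }
    return de, totals


class StimulusResponseModel:
    """Factorial stimulus-response model over a fold-change matrix.

    Parameters
    ----------
    data : FoldChangeMatrix
        Features x samples of log2 fold changes with the 2x2 design.
    """

    def __init__(self, data: FoldChangeMatrix):
        self.data = data
        conds = data.condition_per_sample()
        self._cols = {c: data.condition_columns(c) for c in CONDITION_LABELS}
        for label, cols in self._cols.items():
            if len(cols) < 2:
                raise InsufficientReplicationError(
                    f"condition {label} has {len(cols)} samples"
                )
        del conds

    @classmethod
    def from_dataframe(
        cls,
        values: pd.DataFrame,
        samples: pd.DataFrame,
        stimulus_names: tuple[str, str] = ("HT", "G"),
    ) -> "StimulusResponseModel":
        return cls(
            FoldChangeMatrix(
                values=values, samples=samples, stimulus_names=stimulus_names
            )
        )

    def fit(
        self,
        alpha: float = 0.05,
        q_threshold: float = 0.05,
        epistasis_alpha: float = 0.05,
        *,
        epistasis_welch: bool = False,
    ) -> "StimulusResponseResults":
        """Fit every feature; BH-adjust; classify; run the epistasis test."""
        for thr in (alpha, q_threshold, epistasis_alpha):
            if not 0 < thr < 1:
                raise ConfigError("thresholds must lie in (0, 1)")
        V = self.data.values
        fits = [
            fit_feature_model(
                {c: V.loc[fid, self._cols[c]].to_numpy(float)
                 for c in CONDITION_LABELS},
                feature_id=fid,
            )
            for fid in V.index
        ]
        q = adjust_fdr_bh(np.array([f.anova_p for f in fits]))
        for f, qi in zip(fits, q):
            f.q = float(qi)
        responder, responder_counts = call_responders(q, q_threshold)
        de, de_totals = stimulus_de_calls(
            np.array([f.coef_p for f in fits]), responder, alpha
        )
        calls = [
            classify_interaction(f.feature_id, f.beta, f.coef_p, bool(r), alpha)
            for f, r in zip(fits, responder)
        ]
        # the epistasis split covers every feature, responder or not
        epi = [
            epistasis_test(
                f.feature_id, f.beta, f.se, f.df_resid, epistasis_alpha,
                welch=epistasis_welch,
            )
            for f in fits
        ]
        return StimulusResponseResults(
            model=self,
            fits=fits,
            calls=calls,
            epistasis=epi,
            de=de,
            de_totals=de_totals,
            responder=responder,
            responder_counts=responder_counts,
            alpha=alpha,
            q_threshold=q_threshold,
            epistasis_alpha=epistasis_alpha,
        )


class StimulusResponseResults:
    """Estimates, classifications and epistasis calls from a fitted model."""

    def __init__(
        self,
        model: StimulusResponseModel,
        fits: list[FeatureModelFit],
        calls: list[InteractionCall],
        epistasis: list[EpistasisResult],
        de: np.ndarray,
        de_totals: dict,
        responder: np.ndarray,
        responder_counts: dict,
        alpha: float,
        q_threshold: float,
        epistasis_alpha: float,
    ):
        self.model = model
        self.fits = fits
        self.calls = calls
        self.epistasis = epistasis
        self.de = de
        self.de_totals = de_totals
        self.responder = responder
        self.responder_counts = responder_counts
        self.alpha = alpha
        self.q_threshold = q_threshold
        self.epistasis_alpha = epistasis_alpha

    # -- tabular views -----------------------------------------------------
    @property
    def fits_frame(self) -> pd.DataFrame:
        a, b = self.model.data.stimulus_names
        names = {"A": a, "B": b, "AB": f"{a}{b}"}
        rows = {"feature_id": [f.feature_id for f in self.fits]}
        for k, c in enumerate(CONDITION_LABELS):
            rows[f"beta_{names[c]}"] = [f.beta[k] for f in self.fits]
        for k, c in enumerate(CONDITION_LABELS):
            rows[f"se_{names[c]}"] = [f.se[k] for f in self.fits]
        for k, c in enumerate(CONDITION_LABELS):
            rows[f"p_{names[c]}"] = [f.coef_p[k] for f in self.fits]
        for k, c in enumerate(CONDITION_LABELS):
            rows[f"dir_{names[c]}"] = [int(f.direction[k]) for f in self.fits]
        rows["df_resid"] = [f.df_resid for f in self.fits]
        rows["F"] = [f.anova_F for f in self.fits]
        rows["anova_p"] = [f.anova_p for f in self.fits]
        rows["q"] = [f.q for f in self.fits]
        rows["responder"] = list(map(bool, self.responder))
        return pd.DataFrame(rows)

    @property
    def calls_frame(self) -> pd.DataFrame:
        return calls_to_frame(self.calls)

    @property
    def epistasis_frame(self) -> pd.DataFrame:
        return epistasis_to_frame(self.epistasis)

    @property
    def class_counts(self) -> dict[str, int]:
        return self.summary_counts()["class_counts"]

    @property
    def n_unclassified(self) -> int:
        return self.class_counts[InteractionClass.UNCLASSIFIED.value]

    @property
    def annotations(self) -> pd.DataFrame:
        """Per-feature class and epistasis flag, for network node annotation."""
        return pd.DataFrame(
            {
                "class": [c.class_label.value for c in self.calls],
                "epistatic": [e.epistatic for e in self.epistasis],
            },
            index=pd.Index([c.feature_id for c in self.calls], name="feature_id"),
        )

    def summary_counts(self) -> dict:
        summary = summarize_classes(self.calls, self.epistasis)
        summary["de_counts"] = dict(self.de_totals)
        summary["responders"] = self.responder_counts["responders"]
        summary["non_responders"] = self.responder_counts["non_responders"]
        return summary

    def summary(self) -> str:
        """Human-readable summary of the fitted model."""
        a, b = self.model.data.stimulus_names
        s = self.summary_counts()
        lines = [
            "Stimulus-response factorial model",
            "=" * 48,
            f"features: {s['n_features']}   "
            f"samples: {self.model.data.n_samples}",
            f"stimuli: {a}, {b} (concurrent {a}{b})",
            f"responder gate: q <= {self.q_threshold} (BH on overall ANOVA p)",
            f"coefficient significance: p < {self.alpha}",
            "",
            f"differentially expressed: {a} {s['de_counts']['A']}, "
            f"{b} {s['de_counts']['B']}, {a}{b} {s['de_counts']['AB']}",
            "",
            "interaction classes:",
        ]
        label_names = {
            "A_DOMINANT": f"{a}-dominant",
            "B_DOMINANT": f"{b}-dominant",
            "NER": "non-specific environmental response",
            "DISCORDANT": "discordant",
            "SUPPRESSION": "suppression",
            "NON_RESPONDER": "non-responder",
            "UNCLASSIFIED": "unclassified",
        }
        for key, name in label_names.items():
            count = s["class_counts"][key]
            if key == "UNCLASSIFIED" and count == 0:
                continue
            lines.append(f"  {name:<38s} {count:>6d}")
        lines += [
            "",
            f"environmental epistasis (p <= {self.epistasis_alpha}): "
            f"{s['epistatic']} affected, {s['non_epistatic']} not affected",
        ]
        if s["class_counts"]["UNCLASSIFIED"] > 0:
            lines.append(
                "warning: responders with no individually significant "
                f"coefficient: {s['class_counts']['UNCLASSIFIED']}"
            )
        return "\n".join(lines)

    def tables(self) -> dict[str, pd.DataFrame]:
        """Result tables keyed by file stem (stable order for reruns)."""
        s = self.summary_counts()
        summary_rows = [("n_features", s["n_features"])]
        summary_rows += [(f"class_{k}", v) for k, v in s["class_counts"].items()]
        summary_rows += [(f"de_{k}", v) for k, v in s["de_counts"].items()]
        summary_rows += [
            ("responders", s["responders"]),
            ("non_responders", s["non_responders"]),
            ("epistatic", s["epistatic"]),
            ("non_epistatic", s["non_epistatic"]),
        ]
        return {
            "feature_models": self.fits_frame,
            "interaction_classes": self.calls_frame,
            "epistasis": self.epistasis_frame,
            "summary_counts": pd.DataFrame(summary_rows, columns=["key", "value"]),
        }
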