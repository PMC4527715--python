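"""Environmental-interaction classes and the environmental-epistasis test.

Two concurrent binary stimuli (A, B) and their combination (AB) give each
feature a triplet of per-condition responses. Coding each response as
significant-up (+1), significant-down (-1) or not significant (0) yields 27
possible states; responders among them fall into five interaction classes
that mirror classical gene-interaction categories:

NER (non-specific environmental response)
    all three conditions significant in the same direction (2 patterns);
A-dominant / B-dominant
    the combined response matches one stimulus in direction and significance
    while the other stimulus is absent or overridden (4 patterns each);
SUPPRESSION
    a single-stimulus response abolished under the concurrent condition,
    i.e. AB not significant while A or B is (8 patterns);
DISCORDANT
    a significant combined response matched in direction by neither single
    stimulus (8 patterns).

The remaining all-non-significant state is either a NON_RESPONDER (when the
overall test is not significant) or UNCLASSIFIED (a responder by the joint
F test with no individually significant coefficient).

Environmental epistasis is non-additivity: the combined response differs
from the sum of the single-stimulus responses. It is tested per feature by a
t statistic on (beta_A + beta_B) - beta_AB with the combined standard error
sqrt(se_A^2 + se_B^2 + se_AB^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError


class InteractionClass(str, Enum):
    NON_RESPONDER = "NON_RESPONDER"
    A_DOMINANT = "A_DOMINANT"
    B_DOMINANT = "B_DOMINANT"
    NER = "NER"
    DISCORDANT = "DISCORDANT"
    SUPPRESSION = "SUPPRESSION"
    UNCLASSIFIED = "UNCLASSIFIED"


# all 27 (state_A, state_B, state_AB) triplets over {-1, 0, +1};
# pattern_id = 9*(sA+1) + 3*(sB+1) + (sAB+1)
ALL_PATTERNS: list[tuple[int, int, int]] = list(product((-1, 0, 1), repeat=3))


def pattern_id(state: tuple[int, int, int]) -> int:
    """Integer id (0..26) of a sign/significance state triplet."""
    s_a, s_b, s_ab = state
    return 9 * (s_a + 1) + 3 * (s_b + 1) + (s_ab + 1)


def classify_state(
    state: tuple[int, int, int], responder: bool = True
) -> InteractionClass:
    """Classify a (A, B, AB) sign/significance state triplet.

    Rules are evaluated in a fixed order; NER precedes the dominance rules,
    which resolves the single overlap (an all-significant same-direction
    state satisfies both dominance clauses).
    """
    s_a, s_b, s_ab = state
    if not responder:
        return InteractionClass.NON_RESPONDER
    sig_a, sig_b, sig_ab = s_a != 0, s_b != 0, s_ab != 0
    if sig_a and sig_b and sig_ab and s_a == s_b == s_ab:
        return InteractionClass.NER
    if sig_a and sig_ab and s_a == s_ab and (not sig_b or s_b != s_ab):
        return InteractionClass.A_DOMINANT
    if sig_b and sig_ab and s_b == s_ab and (not sig_a or s_a != s_ab):
        return InteractionClass.B_DOMINANT
    if not sig_ab and (sig_a or sig_b):
        return InteractionClass.SUPPRESSION
    if sig_ab and (not sig_a or s_a != s_ab) and (not sig_b or s_b != s_ab):
        return InteractionClass.DISCORDANT
    return InteractionClass.UNCLASSIFIED


def patterns_for_class(cls: InteractionClass) -> list[tuple[int, int, int]]:
    """Admissible sign/significance triplets of an interaction class."""
    if cls == InteractionClass.NON_RESPONDER:
        return [(0, 0, 0)]
    return [s for s in ALL_PATTERNS if classify_state(s, responder=True) == cls]


def pattern_class_counts() -> dict[InteractionClass, int]:
    """Class sizes over the exhaustive 27-state table (responders)."""
    counts: dict[InteractionClass, int] = {}
    for state in ALL_PATTERNS:
        cls = classify_state(state, responder=True)
        counts[cls] = counts.get(cls, 0) + 1
    return counts


@dataclass
class InteractionCall:
    feature_id: str
    class_label: InteractionClass
    pattern_id: int
    ner_direction: str  # "up", "down" or "n/a"


@dataclass
class EpistasisResult:
    feature_id: str
    sum_effect: float
    se_sum: float
    t_stat: float
    df: float
    p: float
    epistatic: bool
    degenerate: bool = False


def classify_interaction(
    feature_id: str,
    beta: np.ndarray,
    coef_p: np.ndarray,
    responder: bool,
    alpha: float = 0.05,
) -> InteractionCall:
    """Classify one feature from its three condition effects and p-values.

    ``beta`` and ``coef_p`` are ordered (A, B, AB). Significance is strict
    (``p < alpha``); direction is the sign of the estimate.
    """
    sig = np.asarray(coef_p) < alpha
    direction = np.sign(np.asarray(beta)).astype(int)
    state = tuple(int(d) if s else 0 for d, s in zip(direction, sig))
    cls = classify_state(state, responder=responder)
    if cls == InteractionClass.NER:
        ner_dir = "up" if state[0] > 0 else "down"
    else:
        ner_dir = "n/a"
    return InteractionCall(
        feature_id=feature_id,
        class_label=cls,
        pattern_id=pattern_id(state),
        ner_direction=ner_dir,
    )


def epistasis_test(
    feature_id: str,
    beta: np.ndarray,
    se: np.ndarray,
    df: float,
    alpha: float = 0.05,
    *,
    welch: bool = False,
) -> EpistasisResult:
    """Test whether the combined response deviates from additivity.

    The single-stimulus effects are summed; the deviation
    ``(beta_A + beta_B) - beta_AB`` is compared to zero with the combined
    standard error ``sqrt(se_A^2 + se_B^2 + se_AB^2)``. Degrees of freedom
    default to the feature model's residual df; ``welch=True`` switches to a
    Satterthwaite approximation over the three per-condition components.
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    sum_effect = beta[0] + beta[1]
    se_sum = float(np.sqrt(se[0] ** 2 + se[1] ** 2))
    delta = sum_effect - beta[2]
    se_comb = float(np.sqrt(np.sum(se**2)))
    if se_comb == 0.0:
        # noiseless degenerate input: decide by the deviation itself
        epi = abs(delta) > 1e-9
        return EpistasisResult(
            feature_id=feature_id,
            sum_effect=float(sum_effect),
            se_sum=se_sum,
            t_stat=np.inf if epi else 0.0,
            df=df,
            p=0.0 if epi else 1.0,
            epistatic=epi,
            degenerate=True,
        )
    if welch:
        num = np.sum(se**2) ** 2
        den = np.sum(se**4 / df)
        use_df = float(num / den) if den > 0 else df
    else:
        use_df = df
    t = float(delta / se_comb)
    p = float(2.0 * stats.t.sf(abs(t), use_df))
    return EpistasisResult(
        feature_id=feature_id,
        sum_effect=float(sum_effect),
        se_sum=se_sum,
        t_stat=t,
        df=use_df,
        p=p,
        epistatic=p <= alpha,
    )


def summarize_classes(
    calls: list[InteractionCall], epi: list[EpistasisResult]
) -> dict:
    """Count features per interaction class and per epistasis flag.

    The two partitions must cover the same feature set; class counts and the
    epistatic/non-epistatic split each sum to the total feature count.
    """
    call_ids = [c.feature_id for c in calls]
    epi_ids = [e.feature_id for e in epi]
    if sorted(call_ids) != sorted(epi_ids):
        raise ConfigError("classification and epistasis feature sets differ")
    class_counts = {c.value: 0 for c in InteractionClass}
    for call in calls:
        class_counts[call.class_label.value] += 1
    n_epi = sum(e.epistatic for e in epi)
    return {
        "n_features": len(calls),
        "class_counts": class_counts,
        "epistatic": n_epi,
        "non_epistatic": len(epi) - n_epi,
    }


def calls_to_frame(calls: list[InteractionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [c.feature_id for c in calls],
            "class": [c.class_label.value for c in calls],
            "pattern_id": [c.pattern_id for c in calls],
            "ner_direction": [c.ner_direction for c in calls],
        }
    )


def epistasis_to_frame(results: list[EpistasisResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [e.feature_id for e in results],
            "sum_effect": [e.sum_effect for e in results],
            "se_sum": [e.se_sum for e in results],
            "t": [e.t_stat for e in results],
            "df": [e.df for e in results],
            "p": [e.p for e in results],
            "epistatic": [e.epistatic for e in results],
        }
    )
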