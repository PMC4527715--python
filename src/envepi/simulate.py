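"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the statistical structure of a two-stimulus factorial
quantitative-proteomics experiment: per-feature true mean log2 fold changes
under stimulus A, stimulus B and the concurrent condition AB, chosen from the
theoretical sign/significance pattern of an interaction class, plus Gaussian
replicate noise. True effects take values in {0, +effect_size, -effect_size}
only, which makes the truth -> pattern map unambiguous and classification
recovery directly testable. Growth curves are exponential with an optional
lag and stationary plateau, with log-normal noise on OD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import InteractionClass, pattern_id, patterns_for_class
from .exceptions import ConfigError
from .io import FoldChangeMatrix, GrowthCurve

DEFAULT_CLASS_MIX = {
    InteractionClass.NON_RESPONDER: 1 / 6,
    InteractionClass.A_DOMINANT: 1 / 6,
    InteractionClass.B_DOMINANT: 1 / 6,
    InteractionClass.NER: 1 / 6,
    InteractionClass.DISCORDANT: 1 / 6,
    InteractionClass.SUPPRESSION: 1 / 6,
}


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated feature."""

    feature_id: str
    class_label: InteractionClass
    pattern_id: int
    mu_a: float
    mu_b: float
    mu_ab: float

    @property
    def epistatic(self) -> bool:
        """True iff the combined mean deviates from additivity."""
        return abs(self.mu_ab - (self.mu_a + self.mu_b)) > 1e-12


@dataclass
class GeneratorConfig:
    """Parameters of the fold-change generator.

    effect_size is the magnitude of a nonzero true mean (log2 units);
    noise_sd the replicate standard deviation (log2 units). The defaults
    (effect 1.0, sd 0.2, 3 replicates) mirror a well-powered iTRAQ-style
    design in which a two-fold change is ~5 replicate SDs.
    """

    n_features: int = 500
    class_mix: dict[InteractionClass, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )
    effect_size: float = 1.0
    noise_sd: float = 0.2
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ConfigError("n_features must be >= 1")
        mix = {InteractionClass(k): float(v) for k, v in self.class_mix.items()}
        if any(v < 0 for v in mix.values()):
            raise ConfigError("class_mix proportions must be nonnegative")
        total = sum(mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class_mix must sum to 1 (got {total})")
        self.class_mix = mix
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")


def _largest_remainder_counts(n: int, mix: dict) -> dict:
    """Apportion n features to classes by largest-remainder rounding."""
    keys = list(mix)
    quotas = np.array([mix[k] * n for k in keys])
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    for idx in order[:remainder]:
        counts[idx] += 1
    return dict(zip(keys, counts))


def generate_truth_table(config: GeneratorConfig) -> list[SyntheticTruth]:
    """Draw per-feature true means from the theoretical pattern table.

    Class counts follow ``class_mix`` after largest-remainder rounding;
    within a class the sign/significance pattern is sampled uniformly over
    that class's admissible patterns and means are set to
    {0, +effect_size, -effect_size} accordingly.
    """
    rng = np.random.default_rng(config.seed)
    counts = _largest_remainder_counts(config.n_features, config.class_mix)
    width = len(str(config.n_features))
    truths: list[SyntheticTruth] = []
    i = 0
    for cls, count in counts.items():
        patterns = patterns_for_class(cls)
        for _ in range(count):
            state = patterns[rng.integers(len(patterns))]
            mu = tuple(s * config.effect_size for s in state)
            truths.append(
                SyntheticTruth(
                    feature_id=f"F{i:0{width}d}",
                    class_label=cls,
                    pattern_id=pattern_id(state),
                    mu_a=mu[0],
                    mu_b=mu[1],
                    mu_ab=mu[2],
                )
            )
            i += 1
    return truths


def truth_to_frame(truths: list[SyntheticTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [t.feature_id for t in truths],
            "class": [t.class_label.value for t in truths],
            "pattern_id": [t.pattern_id for t in truths],
            "mu_a": [t.mu_a for t in truths],
            "mu_b": [t.mu_b for t in truths],
            "mu_ab": [t.mu_ab for t in truths],
            "epistatic": [t.epistatic for t in truths],
        }
    )


def _sample_frame(
    n_replicates: int, stimulus_names: tuple[str, str]
) -> pd.DataFrame:
    a, b = stimulus_names
    ids, sa, sb, rep = [], [], [], []
    for label, (ia, ib) in ((a, (1, 0)), (b, (0, 1)), (f"{a}{b}", (1, 1))):
        for r in range(1, n_replicates + 1):
            ids.append(f"{label}_r{r}")
            sa.append(ia)
            sb.append(ib)
            rep.append(r)
    return pd.DataFrame(
        {"stimulus_a": sa, "stimulus_b": sb, "replicate": rep},
        index=pd.Index(ids, name="sample_id"),
    )


def simulate_fold_changes(
    truths: list[SyntheticTruth],
    config: GeneratorConfig,
    *,
    stimulus_names: tuple[str, str] = ("HT", "G"),
) -> FoldChangeMatrix:
    """Replicate fold changes: true condition mean + Normal(0, noise_sd^2)."""
    if not truths:
        raise ConfigError("truth table is empty")
    rng = np.random.default_rng(config.seed + 1)  # decoupled from truth draws
    n = len(truths)
    r = config.n_replicates
    mu = np.array([[t.mu_a, t.mu_b, t.mu_ab] for t in truths])
    means = np.repeat(mu, r, axis=1)  # columns: A x r, B x r, AB x r
    noise = rng.normal(0.0, config.noise_sd, size=means.shape)
    samples = _sample_frame(r, stimulus_names)
    values = pd.DataFrame(
        means + noise,
        index=pd.Index([t.feature_id for t in truths], name="feature_id"),
        columns=samples.index,
    )
    return FoldChangeMatrix(
        values=values, samples=samples, stimulus_names=stimulus_names
    )


def simulate_additive_null(
    n_features: int,
    noise_sd: float = 0.2,
    n_replicates: int = 3,
    seed: int = 0,
    *,
    effect_range: tuple[float, float] = (-1.0, 1.0),
) -> tuple[FoldChangeMatrix, pd.DataFrame]:
    """Fold changes under exact additivity (mu_AB = mu_A + mu_B).

    Single-stimulus means are drawn Uniform(effect_range); pass
    ``effect_range=(0, 0)`` for an all-null dataset. Used for type-I-error
    calibration of the epistasis test. Returns the matrix and the truth
    table of true means.
    """
    if n_features < 1:
        raise ConfigError("n_features must be >= 1")
    rng = np.random.default_rng(seed)
    mu_a = rng.uniform(*effect_range, size=n_features)
    mu_b = rng.uniform(*effect_range, size=n_features)
    mu_ab = mu_a + mu_b
    width = len(str(n_features))
    ids = [f"N{i:0{width}d}" for i in range(n_features)]
    means = np.repeat(
        np.column_stack([mu_a, mu_b, mu_ab]), n_replicates, axis=1
    )
    noise = rng.normal(0.0, noise_sd, size=means.shape)
    samples = _sample_frame(n_replicates, ("HT", "G"))
    values = pd.DataFrame(
        means + noise, index=pd.Index(ids, name="feature_id"), columns=samples.index
    )
    truth = pd.DataFrame(
        {"feature_id": ids, "mu_a": mu_a, "mu_b": mu_b, "mu_ab": mu_ab}
    )
    return FoldChangeMatrix(values=values, samples=samples), truth


def simulate_growth_curves(
    doubling_time_minutes: float,
    od0: float = 0.05,
    lag_minutes: float = 0.0,
    duration_minutes: float = 600.0,
    interval_minutes: float = 3.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    plateau_od: float | None = None,
    condition_label: str = "",
) -> GrowthCurve:
    """Exponential growth curve with optional lag, plateau and OD noise.

    OD(t) = od0 for t < lag, then od0 * 2^((t - lag)/doubling_time), capped
    at ``plateau_od``. Noise is log-normal: Normal(0, noise_sd^2) added to
    log OD. Sampling every 3 minutes emulates a plate-reader time course.
    """
    if doubling_time_minutes <= 0:
        raise ConfigError("doubling_time_minutes must be > 0")
    if od0 <= 0:
        raise ConfigError("od0 must be > 0")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_minutes + interval_minutes / 2, interval_minutes)
    grown = np.clip(times - lag_minutes, 0.0, None)
    od = od0 * np.exp2(grown / doubling_time_minutes)
    if plateau_od is not None:
        od = np.minimum(od, plateau_od)
    if noise_sd > 0:
        od = np.exp(np.log(od) + rng.normal(0.0, noise_sd, size=od.shape))
    return GrowthCurve(times=times, od=od, condition_label=condition_label)
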