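"""End-to-end orchestration: ingest -> model -> classify -> network -> reports.

A single :class:`PipelineConfig` (YAML-loadable) drives deterministic runs;
every output table is a TSV with stable row and column order, and a JSON run
log records package versions, thresholds, the seed and input digests so a
rerun on identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigError
from .io import (
    FoldChangeMatrix,
    read_fold_change_table,
    write_results,
)
from .model import StimulusResponseModel, StimulusResponseResults
from .network import (
    CoexpressionNetworkResults,
    NetworkConfig,
    SparsePartialCorrelationModel,
)


@dataclass
class PipelineConfig:
    matrix_path: str | None = None
    schema_path: str | None = None
    out_dir: str = "envepi_out"
    alpha_coef: float = 0.05
    q_threshold: float = 0.05
    epistasis_alpha: float = 0.05
    require_complete: bool = True
    stimulus_names: tuple[str, str] = ("HT", "G")
    network: NetworkConfig = field(default_factory=NetworkConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for thr in (self.alpha_coef, self.q_threshold, self.epistasis_alpha):
            if not 0 < thr < 1:
                raise ConfigError("thresholds must lie in (0, 1)")
        self.stimulus_names = tuple(self.stimulus_names)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        net = NetworkConfig(**raw.pop("network", {}))
        return cls(network=net, **raw)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_run_log(out_dir: Path, entry: dict) -> None:
    import numpy, scipy, statsmodels  # noqa: PLC0415

    entry = {
        "versions": {
            "envepi": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
        **entry,
    }
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(entry, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_matrix(config: PipelineConfig) -> FoldChangeMatrix:
    if config.matrix_path is None:
        raise ConfigError("matrix_path is required")
    schema = None
    if config.schema_path:
        with open(config.schema_path) as fh:
            schema = yaml.safe_load(fh)
    return read_fold_change_table(
        config.matrix_path,
        schema,
        require_complete=config.require_complete,
        stimulus_names=config.stimulus_names,
    )


def run_interaction_pipeline(
    config: PipelineConfig, matrix: FoldChangeMatrix | None = None
) -> StimulusResponseResults:
    """Read -> fit -> BH -> classify -> epistasis -> write tables + run log."""
    if matrix is None:
        matrix = load_matrix(config)
    results = StimulusResponseModel(matrix).fit(
        alpha=config.alpha_coef,
        q_threshold=config.q_threshold,
        epistasis_alpha=config.epistasis_alpha,
    )
    out_dir = Path(config.out_dir)
    write_results(results.tables(), out_dir)
    warnings = []
    if results.n_unclassified > 0:
        warnings.append(
            f"UNCLASSIFIED responders: {results.n_unclassified}"
        )
    if any(f.zero_variance for f in results.fits):
        n0 = sum(f.zero_variance for f in results.fits)
        warnings.append(f"zero-residual-variance features: {n0}")
    _write_run_log(
        out_dir,
        {
            "stage": "interactions",
            "thresholds": {
                "alpha_coef": config.alpha_coef,
                "q_threshold": config.q_threshold,
                "epistasis_alpha": config.epistasis_alpha,
            },
            "seed": config.seed,
            "n_features": matrix.n_features,
            "n_dropped_incomplete": matrix.n_dropped,
            "input_digest": _sha256(config.matrix_path)
            if config.matrix_path
            else None,
            "warnings": warnings,
        },
    )
    return results


def run_network_pipeline(
    config: PipelineConfig,
    interaction_results: StimulusResponseResults,
    matrix: FoldChangeMatrix | None = None,
) -> CoexpressionNetworkResults:
    """Normalization chain -> estimation over the tuning grid -> reports."""
    if matrix is None:
        matrix = interaction_results.model.data
    model = SparsePartialCorrelationModel(matrix, config.network)
    net_results = model.fit(annotations=interaction_results.annotations)
    out_dir = Path(config.out_dir)
    tables = net_results.tables()
    tallies = net_results.edge_classes() if net_results.network.n_edges else {}
    hub = net_results.hubs() if net_results.network.n_edges else None
    summary_rows = [("n_nodes", len(net_results.network.node_ids)),
                    ("n_connected_nodes", len(net_results.network.connected_node_ids())),
                    ("n_edges", net_results.network.n_edges),
                    ("tuning", net_results.tuning)]
    summary_rows += [(k, v) for k, v in tallies.items() if k != "n_edges"]
    if hub is not None:
        summary_rows += [
            ("n_hubs", len(hub.hubs)),
            ("hub_jaccard", hub.jaccard),
            ("hub_wilcoxon_p", hub.wilcoxon_p),
        ]
    tables["network_summary"] = pd.DataFrame(
        summary_rows, columns=["key", "value"]
    )
    write_results(tables, out_dir)
    _write_run_log(
        out_dir,
        {
            "stage": "network",
            "pipeline_order": "pqn->glog->standardize->estimate->threshold",
            "tuning": net_results.tuning,
            "tuning_grid": list(config.network.tuning_grid),
            "seed": config.seed,
        },
    )
    return net_results
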