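"""Configuration-driven end-to-end runs: kernel → estimator → metrics.

A :class:`RunConfig` (one YAML document, unknown keys rejected) names the
input, the kernel and its parameters, the estimator parameters and the
requested metrics; :func:`run_pipeline` executes the stages, writes every
artifact (transition matrix as MTX, memberships, fate table, rankings,
metrics JSON) and records provenance (config, seed, package version,
input checksums).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import ExpressionDataset, NeighborGraph
from .estimator import FateMap
from .io import read_dataset, write_transition_matrix
from .kernels import (
    PseudotimeVector,
    SoftSchemeParams,
    assemble_global_chain,
    adaptive_threshold,
    cytotrace_pseudotime,
    cytotrace_score,
    pseudotime_transition_matrix,
    sinkhorn_coupling,
    velocity_transition_matrix,
)
from .labeling import fit_kinetic_rates, rates_to_velocity

log = logging.getLogger("fatechain")

_KNOWN_KERNELS = ("pseudotime", "cytotrace", "velocity", "realtime", "labeling")


@dataclass
class RunConfig:
    """Serializable description of one reproducible run."""

    input_path: str
    input_format: str = "mtx_dir"
    kernel: str = "pseudotime"
    kernel_params: dict = field(default_factory=dict)
    embedding: str = "pca"
    n_neighbors: int = 15
    n_macrostates: int = 3
    n_representatives: int = 30
    stability_threshold: float = 0.96
    metrics: list = field(default_factory=list)
    cluster_key: str = "cluster"
    seed: int = 0
    outdir: str = "fatechain_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.kernel not in _KNOWN_KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}; choose from {_KNOWN_KERNELS}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    if path.is_dir():
        for f in sorted(path.rglob("*")):
            if f.is_file():
                h.update(f.name.encode())
                h.update(f.read_bytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


def _build_kernel(config: RunConfig, ds: ExpressionDataset, graph: NeighborGraph):
    p = dict(config.kernel_params)
    if config.kernel == "pseudotime":
        col = p.pop("pseudotime_key", "pseudotime")
        if col not in ds.cell_meta:
            raise ValueError(f"pseudotime column {col!r} missing from cell metadata")
        pt = PseudotimeVector(ds.cell_meta[col].to_numpy(dtype=float))
        scheme = p.pop("scheme", "soft")
        params = SoftSchemeParams(b=p.pop("b", 10.0), nu=p.pop("nu", 0.5))
        return pseudotime_transition_matrix(graph, pt, scheme=scheme, params=params, **p)
    if config.kernel == "cytotrace":
        L = p.pop("n_genes", 200)
        score = cytotrace_score(ds.dense_X(), graph, L=min(L, ds.n_genes))
        pt = cytotrace_pseudotime(score)
        scheme = p.pop("scheme", "soft")
        return pseudotime_transition_matrix(graph, pt, scheme=scheme, **p)
    if config.kernel == "velocity":
        if "velocity" not in ds.layers:
            raise ValueError("velocity kernel requires a 'velocity' layer")
        return velocity_transition_matrix(
            graph, ds.dense_X(), ds.dense_layer("velocity"), **p
        )
    if config.kernel == "labeling":
        rates = fit_kinetic_rates(ds, embedding=config.embedding, **p)
        V = rates_to_velocity(rates, ds.dense_layer("total"))
        return velocity_transition_matrix(graph, ds.dense_layer("total"), V)
    if config.kernel == "realtime":
        if "time" not in ds.cell_meta:
            raise ValueError("realtime kernel requires a 'time' column in cell metadata")
        time = ds.cell_meta["time"].to_numpy(dtype=float)
        Z = ds.embeddings[config.embedding]
        times = np.unique(time)
        couplings = []
        for t0, t1 in zip(times[:-1], times[1:]):
            cp = sinkhorn_coupling(Z[time == t0], Z[time == t1])
            cp.source_time, cp.target_time = float(t0), float(t1)
            couplings.append(cp)
        chain = assemble_global_chain(
            couplings, graph, time, conn_weight=p.pop("conn_weight", 0.2),
            self_transitions=p.pop("self_transitions", "all"),
        )
        thresh = p.pop("threshold", "auto")
        if thresh is not None:
            chain = adaptive_threshold(chain, thresh)
        return chain.T
    raise ValueError(config.kernel)  # pragma: no cover


def run_pipeline(config: RunConfig) -> Path:
    """Execute kernel → estimator → metrics; return the artifact directory."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.random.seed(config.seed % (2**31))

    log.info("stage=read input=%s", config.input_path)
    ds = read_dataset(config.input_path, config.input_format)
    log.info("stage=read n_cells=%d n_genes=%d", ds.n_cells, ds.n_genes)
    Z = ds.embeddings[config.embedding]
    graph = NeighborGraph.from_embedding(Z, n_neighbors=min(config.n_neighbors, ds.n_cells - 1))

    log.info("stage=kernel kernel=%s", config.kernel)
    T = _build_kernel(config, ds, graph)
    write_transition_matrix(T, outdir / "transition_matrix.mtx", cell_ids=ds.cell_ids)

    log.info("stage=estimator n_macrostates=%d", config.n_macrostates)
    model = FateMap(T, dataset=ds, cluster_key=config.cluster_key)
    res = model.fit(
        config.n_macrostates,
        stability_threshold=config.stability_threshold,
        n_representatives=config.n_representatives,
    )
    pd.DataFrame(
        res.macrostates.memberships, index=ds.cell_ids, columns=res.macrostates.labels
    ).to_csv(outdir / "macrostate_memberships.tsv", sep="\t")
    if res.fate is not None:
        res.fate.to_frame(ds.cell_ids).to_csv(outdir / "fate_probabilities.tsv", sep="\t")

    metrics_out: dict = {"terminal_states": res.terminal_labels}
    if "purity" in config.metrics:
        metrics_out["purity"] = {
            res.macrostates.labels[s]: res.state_purity(s) for s in res.terminal_states
        }
    (outdir / "metrics.json").write_text(json.dumps(metrics_out, indent=2))
    (outdir / "summary.txt").write_text(res.summary() + "\n")

    provenance = {
        "config": asdict(config),
        "seed": config.seed,
        "version": __version__,
        "input_checksum": _checksum(Path(config.input_path)),
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    log.info("stage=done outdir=%s", outdir)
    return outdir
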