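"""Declarative run configuration and the staged pipeline driver."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .database import load_database
from .inference import (
    InferenceParams,
    aggregate_pathways,
    information_flow,
    permutation_test,
)
from .io import network_to_frame, read_expression, read_labels, tensor_to_frame
from .markers import identify_overexpressed
from .centrality import centrality_scores

log = logging.getLogger("commscape")

STAGES = ("ingest", "de", "infer", "centrality", "patterns", "similarity")
STAGE_DEPS = {
    "de": ["ingest"],
    "infer": ["ingest"],
    "centrality": ["infer"],
    "patterns": ["infer"],
    "similarity": ["infer"],
}


@dataclass
class RunConfig:
    db_path: str
    matrix_path: str
    labels_path: str
    out_dir: str
    genes_path: str | None = None
    cells_path: str | None = None
    dialect: str = "matrix_market"
    db_dialect: str = "tsv"
    params: InferenceParams = field(default_factory=InferenceParams)
    use_de_filter: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = InferenceParams(**raw.pop("params", {}))
        return cls(params=params, **raw)

    def validate(self) -> None:
        for attr in ("db_path", "matrix_path", "labels_path"):
            p = getattr(self, attr)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p}")


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in order; returns the run manifest.

    Stage dependencies are checked up front; outputs are TSVs under
    ``config.out_dir`` plus a JSON manifest echoing parameters and seed so
    a rerun with the same config reproduces identical files.
    """
    stages = list(stages or STAGES[:3])
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
        for dep in STAGE_DEPS.get(s, []):
            if dep not in stages:
                raise ValueError(f"stage {s!r} requires stage {dep!r}")
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "params": {**config.params.__dict__},
        "stages": stages,
        "outputs": [],
    }

    expr = grouping = db = de = ct = nets = None
    if "ingest" in stages:
        log.info("ingest: reading expression, labels and database")
        expr = read_expression(
            config.matrix_path, config.genes_path, config.cells_path, config.dialect
        )
        grouping = read_labels(config.labels_path)
        db = load_database(config.db_path, config.db_dialect)
    if "de" in stages or (config.use_de_filter and "infer" in stages):
        de = identify_overexpressed(expr, grouping, db, alpha=config.params.alpha)
        p = out / "de.tsv"
        de.table.to_csv(p, sep="\t", index=False)
        manifest["outputs"].append(str(p))
    if "infer" in stages:
        log.info("infer: permutation test with M=%d", config.params.M)
        ct = permutation_test(expr, grouping, db, de=de, params=config.params)
        p = out / "tensor.tsv"
        tensor_to_frame(ct).to_csv(p, sep="\t", index=False)
        manifest["outputs"].append(str(p))
        nets = aggregate_pathways(ct, db, config.params.alpha)
        for net in nets:
            p = out / f"pathway_{net.pathway}.tsv"
            network_to_frame(net).to_csv(p, sep="\t", index=False)
            manifest["outputs"].append(str(p))
        manifest["information_flow"] = {
            net.pathway: information_flow(net) for net in nets
        }
    if "centrality" in stages:
        for net in nets:
            p = out / f"centrality_{net.pathway}.tsv"
            centrality_scores(net).to_csv(p, sep="\t")
            manifest["outputs"].append(str(p))
    if "patterns" in stages and nets:
        from .patterns import build_role_matrix, nmf_factorize, select_pattern_number

        for direction in ("outgoing", "incoming"):
            role = build_role_matrix(nets, direction)
            try:
                R, diag = select_pattern_number(role, seed=config.seed)
                dec = nmf_factorize(role, R, seed=config.seed)
            except ValueError as e:
                log.warning("patterns (%s) skipped: %s", direction, e)
                continue
            import pandas as pd

            pw = out / f"patterns_{direction}_W.tsv"
            pd.DataFrame(dec.W, index=role.group_names).to_csv(pw, sep="\t")
            ph = out / f"patterns_{direction}_H.tsv"
            pd.DataFrame(dec.H, columns=role.signal_names).to_csv(ph, sep="\t")
            manifest["outputs"] += [str(pw), str(ph)]
    if "similarity" in stages and nets and len(nets) >= 3:
        from .similarity import embed_manifold, similarity_matrix, snn_smooth
        import pandas as pd

        S = similarity_matrix(nets, kind="functional")
        names = [n.pathway for n in nets]
        emb = embed_manifold(snn_smooth(S), names, seed=config.seed)
        p = out / "embedding.tsv"
        pd.DataFrame(emb.coords, index=names, columns=["x", "y"]).to_csv(p, sep="\t")
        manifest["outputs"].append(str(p))

    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    manifest["manifest_path"] = str(mpath)
    return manifest
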