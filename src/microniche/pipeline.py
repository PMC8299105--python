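"""End-to-end orchestration: simulate/load -> rarefy -> classify -> network
-> topology -> path effects, with a run manifest and per-stage seeds.

One master seed deterministically derives a child seed per stage (by
hashing the stage name), so any stage can be re-run in isolation and the
composition of stage subcommands is byte-identical to the monolithic run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import derive_seed
from . import io as cio
from .simulate import (SyntheticSpec, generate_community, generate_sem_dataset,
                       DEFAULT_PATH_COEFFICIENTS)
from .niche import NicheBreadthClassifier
from .network import EnsembleNetworkInference, write_edges_tsv, write_graphml
from .topology import NetworkTopology, regress, compare_degree_groups
from .path import PathAnalysis, parse_dag_file, write_effects_tsv

logger = logging.getLogger("microniche.pipeline")

STAGES = ("simulate", "rarefy", "classify", "network", "topology", "effects")


@dataclass
class PipelineConfig:
    """Flat pipeline configuration (file keys use dots for nesting)."""

    otu_table: str | None = None
    metadata: str | None = None
    synthetic: bool = False
    synthetic_params: dict = field(default_factory=dict)
    rarefy_depth: int | None = None
    classifier_params: dict = field(default_factory=dict)
    network_params: dict = field(default_factory=dict)
    dag_file: str | None = None
    sem_data: str | None = None
    effects_bootstrap: int = 1000
    outdir: str = "microniche_out"
    seed: int = 0
    verbosity: str = "INFO"

    def validate(self):
        has_files = self.otu_table is not None or self.metadata is not None
        if self.synthetic and has_files:
            raise ValueError(
                "config must provide either input paths or a synthetic spec, "
                "not both")
        if not self.synthetic:
            if self.otu_table is None or self.metadata is None:
                raise ValueError(
                    "config needs otu_table and metadata paths (or synthetic "
                    "= true)")
        return self


def _parse_value(v: str):
    s = v.strip()
    if s.lower() in ("true", "false"):
        return s.lower() == "true"
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    return s


def read_config(path) -> PipelineConfig:
    """Read the flat ``key = value`` configuration file."""
    cfg = PipelineConfig()
    with open(path, "rt", encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {ln}: expected key = value")
            key, val = (s.strip() for s in line.split("=", 1))
            value = _parse_value(val)
            if key.startswith("synthetic."):
                cfg.synthetic_params[key.split(".", 1)[1]] = value
                cfg.synthetic = True
            elif key == "synthetic":
                cfg.synthetic = bool(value)
            elif key.startswith("classify."):
                cfg.classifier_params[key.split(".", 1)[1]] = value
            elif key.startswith("network."):
                cfg.network_params[key.split(".", 1)[1]] = value
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                raise ValueError(f"{path}: line {ln}: unknown key {key!r}")
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _setup_logging(verbosity: str):
    logging.basicConfig(
        level=getattr(logging, verbosity.upper(), logging.INFO),
        format="%(asctime)s [%(name)s] %(levelname)s %(message)s",
        datefmt="%Y-%m-%dT%H:%M:%S",
        force=False,
    )


def default_dag_text() -> str:
    lines = ["# default path diagram: space -> climate -> fungi -> coexistence"]
    for (a, b) in DEFAULT_PATH_COEFFICIENTS:
        lines.append(f"{a} -> {b}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    spec = SyntheticSpec(**{**cfg.synthetic_params,
                            "seed": derive_seed(cfg.seed, "simulate")})
    table, meta, truth = generate_community(spec)
    cio.write_otu_table(table, outdir / "otu_table.tsv")
    cio.write_metadata(meta, outdir / "metadata.tsv")
    with open(outdir / "truth_archetypes.tsv", "wt") as fh:
        fh.write("otu_id\tarchetype\n")
        for o in table.otu_ids:
            fh.write(f"{o}\t{truth.archetype[o]}\n")
    with open(outdir / "truth_edges.tsv", "wt") as fh:
        fh.write("otu_a\totu_b\n")
        for a, b in sorted(truth.true_edges):
            fh.write(f"{a}\t{b}\n")
    return {"n_otus": table.n_otus, "n_samples": table.n_samples}


def stage_rarefy(cfg: PipelineConfig, outdir: Path) -> dict:
    src = Path(cfg.otu_table) if cfg.otu_table else outdir / "otu_table.tsv"
    if not src.exists():
        raise FileNotFoundError(
            f"{src} not found (produced by the 'simulate' subcommand or "
            "given as otu_table)")
    table = cio.read_otu_table(src)
    dropped = []
    if cfg.rarefy_depth:
        table, dropped = cio.rarefy(
            table, cfg.rarefy_depth, derive_seed(cfg.seed, "rarefy"),
            return_dropped=True)
    cio.write_otu_table(table, outdir / "rarefied_table.tsv")
    return {"depth": cfg.rarefy_depth, "dropped_samples": dropped}


def stage_classify(cfg: PipelineConfig, outdir: Path) -> dict:
    tpath = outdir / "rarefied_table.tsv"
    if not tpath.exists():
        raise FileNotFoundError(
            f"{tpath} not found (produced by the 'rarefy' step of the "
            "pipeline; run 'simulate' / provide otu_table first)")
    mpath = Path(cfg.metadata) if cfg.metadata else outdir / "metadata.tsv"
    if not mpath.exists():
        raise FileNotFoundError(
            f"{mpath} not found (produced by 'simulate' or given as metadata)")
    table = cio.read_otu_table(tpath)
    meta = cio.read_metadata(mpath)
    clf = NicheBreadthClassifier(**cfg.classifier_params)
    clf.fit(table, meta)
    clf.results_.to_csv(outdir / "classification.tsv", sep="\t")
    counts = clf.labels_.value_counts().to_dict()
    return {"label_counts": {str(k): int(v) for k, v in counts.items()},
            "thresholds": clf.thresholds_}


def stage_network(cfg: PipelineConfig, outdir: Path) -> dict:
    tpath = outdir / "rarefied_table.tsv"
    if not tpath.exists():
        raise FileNotFoundError(
            f"{tpath} not found (run the 'rarefy' step / 'simulate' first)")
    table = cio.read_otu_table(tpath)
    params = dict(cfg.network_params)
    params.setdefault("apply_prevalence_filter", True)
    est = EnsembleNetworkInference(
        random_state=derive_seed(cfg.seed, "network"), **params)
    est.fit(table)
    write_edges_tsv(est, outdir / "edges.tsv")
    write_graphml(est, outdir / "network.graphml")
    return {"n_nodes": len(est.nodes_), "n_edges": int(len(est.edges_)),
            "n_pairs_tested": est.n_pairs_,
            "network_params": {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in est.get_params().items()}}


def stage_topology(cfg: PipelineConfig, outdir: Path) -> dict:
    epath = outdir / "edges.tsv"
    cpath = outdir / "classification.tsv"
    if not epath.exists():
        raise FileNotFoundError(f"{epath} not found (produced by 'network')")
    if not cpath.exists():
        raise FileNotFoundError(f"{cpath} not found (produced by 'classify')")
    edges = pd.read_csv(epath, sep="\t")
    niche = pd.read_csv(cpath, sep="\t", index_col="otu_id")
    tpath = outdir / "rarefied_table.tsv"
    table = cio.read_otu_table(tpath)
    import networkx as nx

    g = nx.Graph()
    # nodes = the prevalence-filtered OTU set that entered pair testing
    from .io import prevalence_filter

    params = dict(cfg.network_params)
    g.add_nodes_from(prevalence_filter(
        table,
        params.get("min_occurrence", 4),
        params.get("min_total_reads", 10)).otu_ids)
    for _, r in edges.iterrows():
        g.add_edge(r["otu_a"], r["otu_b"])
    topo = NetworkTopology(random_state=derive_seed(cfg.seed, "topology"))
    topo.fit(g, niche_results=niche)
    topo.report_.to_csv(outdir / "topology.tsv", sep="\t")

    rep = topo.report_.dropna(subset=["B_global"])
    reg_rows = []
    for metric in ("closeness", "betweenness"):
        try:
            r = regress(rep[metric], rep["B_global"])
            reg_rows.append({"response": "B_global", "predictor": metric,
                             "slope": r.slope, "intercept": r.intercept,
                             "r_squared": r.r_squared, "p_value": r.p_value,
                             "n": r.n})
        except ValueError as e:
            logger.warning("regression on %s skipped: %s", metric, e)
    pd.DataFrame(reg_rows).to_csv(outdir / "regressions.tsv", sep="\t",
                                  index=False)

    anova_info = {}
    labeled = rep.dropna(subset=["label"])
    try:
        cmp_ = compare_degree_groups(labeled["degree"], labeled["label"])
        pd.DataFrame(
            [{"group": g_, "mean_degree": cmp_.group_means[g_],
              "letters": cmp_.letters[g_]} for g_ in sorted(cmp_.group_means)]
        ).to_csv(outdir / "anova.tsv", sep="\t", index=False)
        anova_info = {"F": cmp_.f_statistic, "p": cmp_.p_value}
    except ValueError as e:
        logger.warning("degree ANOVA skipped: %s", e)
        pd.DataFrame(columns=["group", "mean_degree", "letters"]).to_csv(
            outdir / "anova.tsv", sep="\t", index=False)
    return {"modularity": topo.modularity_, "anova": anova_info}


def stage_effects(cfg: PipelineConfig, outdir: Path) -> dict:
    if cfg.sem_data:
        data = pd.read_csv(cfg.sem_data, sep="\t")
    elif cfg.synthetic:
        mpath = outdir / "metadata.tsv"
        n = 0
        if mpath.exists():
            n = len(pd.read_csv(mpath, sep="\t"))
        n = max(n, 100)
        data = generate_sem_dataset(
            DEFAULT_PATH_COEFFICIENTS, n=n,
            seed=derive_seed(cfg.seed, "sem-data"))
        data.to_csv(outdir / "sem_data.tsv", sep="\t", index=False)
    else:
        raise FileNotFoundError(
            "no sem_data file configured (provide sem_data or run with a "
            "synthetic spec)")
    if cfg.dag_file:
        edges, composites = parse_dag_file(cfg.dag_file)
    else:
        dag_path = outdir / "default_dag.txt"
        dag_path.write_text(default_dag_text())
        edges, composites = parse_dag_file(dag_path)
    model = PathAnalysis(edges=edges, composites=composites).fit(data)
    model.bootstrap_significance(data, n_bootstrap=cfg.effects_bootstrap,
                                 seed=derive_seed(cfg.seed, "effects"))
    write_effects_tsv(model, outdir / "path_effects.tsv")
    return {"r_squared": model.r_squared_}


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage in order; returns the output directory.

    On a stage failure a ``FAILED`` marker naming the stage is written and
    the exception re-raised; outputs of completed stages are retained.
    """
    cfg = config.validate()
    _setup_logging(cfg.verbosity)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": {k: v for k, v in asdict(cfg).items()},
        "seed": cfg.seed,
        "stage_seeds": {s: derive_seed(cfg.seed, s) for s in STAGES},
        "stages": {},
        "input_checksums": {},
    }
    for key in ("otu_table", "metadata", "sem_data", "dag_file"):
        p = getattr(cfg, key)
        if p:
            manifest["input_checksums"][key] = _sha256(p)

    stage_funcs = [
        ("simulate", stage_simulate) if cfg.synthetic else None,
        ("rarefy", stage_rarefy),
        ("classify", stage_classify),
        ("network", stage_network),
        ("topology", stage_topology),
        ("effects", stage_effects),
    ]
    for item in stage_funcs:
        if item is None:
            continue
        name, func = item
        logger.info("stage %s: start", name)
        t0 = time.perf_counter()
        try:
            info = func(cfg, outdir)
        except Exception as e:
            (outdir / "FAILED").write_text(f"stage {name}: {e}\n")
            logger.error("stage %s failed: %s", name, e)
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        dt = time.perf_counter() - t0
        manifest["stages"][name] = {"seconds": round(dt, 3), **info}
        logger.info("stage %s: done in %.2fs", name, dt)
    with open(outdir / "manifest.json", "wt") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return outdir
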