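"""End-to-end orchestration: simulate -> preprocess -> fit -> network -> core -> stages.

A single YAML-serializable configuration drives the whole chain and a
JSON manifest records every parameter, seed and per-stage summary so a
run is reproducible from its output directory alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fermlink._version import __version__
from fermlink import tables, synthetic, o2pls, association, core, community

log = logging.getLogger("fermlink")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``simulate`` is true (a synthetic dataset is generated from
    the latent spec options in ``simulation``) or the three input paths
    must be given.  Unknown keys are rejected when loading from YAML.
    """

    output_dir: str = "fermlink_out"
    seed: int = 0
    simulate: bool = True
    simulation: dict = field(default_factory=dict)    # LatentSpec overrides
    abundance_path: str | None = None
    flavours_path: str | None = None
    metadata_path: str | None = None
    top_n_per_kingdom: int = 100
    scaling: str = "center"            # O2PLS block scaling: "uv" or "center"
    x_transform: str = "clr"           # "clr" or "relative"
    n_components: int | None = 2       # None -> auto-select by CV
    nx: int = 1
    ny: int = 1
    folds: int = 7
    cv_limit: float = 0.05
    network_threshold: float = 0.7
    high_threshold: float = 0.8
    correlation_method: str = "pearson"
    vip_threshold: float = 1.55
    min_flavour_count: int = 25
    prevalence_fraction: float = 0.9
    amova_permutations: int = 999
    hca_groups: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def validate(self) -> None:
        if not self.simulate:
            missing = [n for n in ("abundance_path", "flavours_path", "metadata_path")
                       if getattr(self, n) is None]
            if missing:
                raise ConfigError(
                    f"simulate is false but input path(s) missing: {missing}"
                )
        if self.x_transform not in ("clr", "relative"):
            raise ConfigError(f"unknown x_transform {self.x_transform!r}")


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _prepare_blocks(cfg: RunConfig, abundance, flavours):
    """Preprocessed X (samples x taxa) and Y (samples x flavours) blocks."""
    rel = tables.to_relative(abundance)
    if cfg.x_transform == "clr":
        X = tables.clr_transform(abundance).T
    else:
        X = rel.values.T
    fl_norm = tables.min_max_normalize(flavours)
    Y = fl_norm.values.T
    return X, Y, rel, fl_norm


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write artefacts plus a manifest.

    Returns the manifest dict.  Any stage error aborts the run with the
    stage name prepended to the propagated message.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool_version": __version__,
        "config": asdict(cfg),
        "config_hash": _config_hash(cfg),
        "stages": {},
    }

    def stage(name):
        log.info("[%s] starting", name)
        return name

    # -- simulate / load ---------------------------------------------------
    name = stage("input")
    try:
        if cfg.simulate:
            spec = synthetic.LatentSpec(seed=cfg.seed, **cfg.simulation)
            ds = synthetic.assemble_dataset(spec)
            abundance, flavours, metadata = ds.abundance, ds.flavours, ds.metadata
            tables.write_abundance(abundance, out / "abundance.tsv")
            tables.write_flavours(flavours, out / "flavours.csv")
            tables.write_metadata(metadata, out / "metadata.csv")
            truth_json = {
                "core_taxa": ds.truth["core_taxa"],
                "core_indices": list(ds.truth["core_indices"]),
                "stage_breaks": list(ds.truth["stage_breaks"]),
                "spec": ds.truth["spec"],
            }
            (out / "truth.json").write_text(json.dumps(truth_json, indent=2))
            manifest["stages"][name] = {"simulated": True,
                                        "n_samples": len(abundance.samples)}
        else:
            abundance = tables.read_abundance(cfg.abundance_path)
            flavours = tables.read_flavours(cfg.flavours_path)
            metadata = tables.read_metadata(cfg.metadata_path)
            ds = None
            manifest["stages"][name] = {"simulated": False,
                                        "n_samples": len(abundance.samples)}
    except Exception as exc:
        raise RuntimeError(f"stage {name}: {exc}") from exc

    # -- preprocess --------------------------------------------------------
    name = stage("preprocess")
    try:
        abundance, flavours, metadata = tables.align_samples(
            abundance, flavours, metadata)
        rel_full = tables.to_relative(abundance)
        top = tables.select_top_taxa(rel_full, cfg.top_n_per_kingdom)
        abundance_top = tables.AbundanceTable(
            abundance.values.loc[top.taxa], abundance.kingdom.loc[top.taxa])
        X, Y, rel, fl_norm = _prepare_blocks(cfg, abundance_top, flavours)
        manifest["stages"][name] = {
            "n_taxa": int(len(top.taxa)), "n_flavours": int(len(flavours.flavours)),
            "x_transform": cfg.x_transform,
        }
    except Exception as exc:
        raise RuntimeError(f"stage {name}: {exc}") from exc

    # -- O2PLS fit ---------------------------------------------------------
    name = stage("fit")
    try:
        if cfg.n_components is None:
            K, nx, ny = o2pls.select_components(
                X, Y, folds=cfg.folds, scale=cfg.scaling, limit=cfg.cv_limit)
        else:
            K, nx, ny = cfg.n_components, cfg.nx, cfg.ny
        model = o2pls.fit_o2pls(X, Y, K, nx=nx, ny=ny, scale=cfg.scaling)
        cv = o2pls.cross_validate(X, Y, K, nx=nx, ny=ny, folds=cfg.folds,
                                  scale=cfg.scaling, limit=cfg.cv_limit)
        vip = pd.Series(model.vip_pred, index=rel.taxa, name="vip_pred")
        vip.to_csv(out / "vip.tsv", sep="\t")
        _dump_model(model, out / "o2pls_model.json")
        manifest["stages"][name] = {
            "K": int(K), "nx": int(nx), "ny": int(ny),
            "r2x_cum": round(model.r2x_cum, 6),
            "r2y_cum": round(model.r2y_cum, 6),
            "q2_cum": round(cv.q2_cum, 6),
            "q2_per_component": [round(float(v), 6) for v in cv.q2_per_component],
        }
    except Exception as exc:
        raise RuntimeError(f"stage {name}: {exc}") from exc

    # -- association network ----------------------------------------------
    name = stage("network")
    try:
        corr = association.correlation_matrix(rel, fl_norm,
                                              method=cfg.correlation_method)
        net = association.threshold_edges(corr, rel, fl_norm,
                                          threshold=cfg.network_threshold)
        net_high = association.threshold_edges(corr, rel, fl_norm,
                                               threshold=cfg.high_threshold)
        association.export_graph(net, out / "edges.tsv", out / "graph.graphml")
        net.genus_counts.to_csv(out / "genus_counts.tsv", sep="\t")
        manifest["stages"][name] = {
            "threshold": cfg.network_threshold,
            "n_edges": int(net.n_edges()),
            "high_threshold": cfg.high_threshold,
            "n_edges_high": int(net_high.n_edges()),
        }
    except Exception as exc:
        raise RuntimeError(f"stage {name}: {exc}") from exc

    # -- core selection ----------------------------------------------------
    name = stage("core")
    try:
        prev = core.prevalence(rel, metadata)
        criteria = core.CoreCriteria(
            prevalence_fraction=cfg.prevalence_fraction,
            vip_threshold=cfg.vip_threshold,
            rho_threshold=cfg.high_threshold,
            min_flavour_count=cfg.min_flavour_count,
        )
        report = core.select_core(prev, vip, net_high, criteria)
        report.records.to_csv(out / "core_report.tsv", sep="\t")
        (out / "venn.json").write_text(json.dumps(report.venn, indent=2))
        manifest["stages"][name] = {
            "core": list(report.core),
            "venn_totals": report.venn["totals"],
            "venn_shared": report.venn["regions"]["OA&AA&VF"],
        }
    except Exception as exc:
        raise RuntimeError(f"stage {name}: {exc}") from exc

    # -- stage statistics --------------------------------------------------
    name = stage("stages")
    try:
        dist = community.hellinger(rel)
        ord_res = community.pcoa(dist, n_components=2)
        ord_res.scores.to_csv(out / "pca_scores.tsv", sep="\t")
        fl_pca = community.pca(fl_norm.values.T, n_components=2)
        t_corr, p_corr = community.correlation_scaled_biplot(
            fl_pca, fl_norm.values.T)
        biplot = pd.concat(
            {"t_corr": t_corr, "p_corr": p_corr}, names=["kind", "id"])
        biplot.to_csv(out / "biplot.tsv", sep="\t")
        Z = community.ward_hca(fl_norm.values.T)
        (out / "hca.newick").write_text(
            community.linkage_to_newick(Z, fl_norm.samples))
        if "stage" in metadata.table.columns:
            part = community.StagePartition(metadata.table["stage"], "metadata")
        else:
            part = community.cut_to_groups(Z, cfg.hca_groups, fl_norm.samples)
        am = community.amova(dist, part, n_permutations=cfg.amova_permutations,
                             seed=cfg.seed)
        (out / "amova.json").write_text(json.dumps({
            "fs": am.fs, "p_value": am.p_value,
            "n_permutations": am.n_permutations}, indent=2))
        rho_acid = rho_alc = None
        if "titratable_acidity" in metadata.table.columns:
            rho_acid = community.spearman_env(
                ord_res.scores.iloc[:, 0], metadata.table["titratable_acidity"])
            rho_alc = community.spearman_env(
                ord_res.scores.iloc[:, 0], metadata.table["alcohol"])
        manifest["stages"][name] = {
            "amova_fs": round(am.fs, 4), "amova_p": am.p_value,
            "spearman_pc1_acidity": None if rho_acid is None else round(rho_acid, 4),
            "spearman_pc1_alcohol": None if rho_alc is None else round(rho_alc, 4),
        }
    except Exception as exc:
        raise RuntimeError(f"stage {name}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("pipeline complete: %s", out)
    return manifest


def _dump_model(model: o2pls.O2PLSModel, path: Path) -> None:
    def mat(M):
        arr = np.asarray(M)
        return {"shape": list(arr.shape), "data": arr.ravel().tolist()}

    payload = {
        "version": __version__,
        "scaling": model.scaling,
        "r2x_cum": model.r2x_cum,
        "r2y_cum": model.r2y_cum,
        "W": mat(model.W), "C": mat(model.C), "B": mat(model.B),
        "T": mat(model.T), "U": mat(model.U),
        "W_orth_x": mat(model.W_orth_x), "P_orth_x": mat(model.P_orth_x),
        "C_orth_y": mat(model.C_orth_y), "P_orth_y": mat(model.P_orth_y),
        "x_center": mat(model.x_center), "x_scale": mat(model.x_scale),
        "y_center": mat(model.y_center), "y_scale": mat(model.y_scale),
        "vip_pred": mat(model.vip_pred),
    }
    path.write_text(json.dumps(payload))
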