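"""End-to-end orchestration: load -> preprocess -> correlate -> associate ->
network -> survival -> enrichment, with a checksummed output manifest.

Every stage writes its artifact to the output directory; the manifest
records sha256 checksums, the resolved configuration and per-stage counts
so a run can be audited and byte-reproduced from config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import association as assoc
from . import correlation as corr
from . import enrichment as enr
from . import io as io_mod
from . import network as net
from . import survival as surv
from .errors import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration of one full run."""

    expression_tumour: str
    expression_normal: str
    clinical: str
    out_dir: str
    gmt: str | None = None
    mr_fraction: float = 0.001
    pcc_threshold: float = 0.7
    min_module_size: int = 12
    alphas: tuple[float, float, float, float] = (0.05, 0.05, 0.05, 0.05)
    eval_days: tuple[float, ...] = (336.0, 672.0, 1008.0, 1344.0, 1680.0)
    n_perm: int = 1000
    gsea_min_size: int = 15
    gsea_max_size: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.mr_fraction < 1:
            raise ConfigurationError("mr_fraction must lie in (0, 1)")
        if not -1 < self.pcc_threshold < 1:
            raise ConfigurationError("pcc_threshold must lie in (-1, 1)")
        if self.min_module_size < 1:
            raise ConfigurationError("min_module_size must be >= 1")
        if any(not 0 < a < 1 for a in self.alphas):
            raise ConfigurationError("alphas must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("alphas", "eval_days"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def validate_inputs(
    expression_tumour: str | Path,
    expression_normal: str | Path,
    clinical: str | Path,
    gmt: str | Path | None = None,
) -> list[str]:
    """Schema report: every violation found, empty list when all is well."""
    violations: list[str] = []
    tumour = normal = clin = None
    try:
        tumour = io_mod.read_expression(expression_tumour)
    except Exception as exc:
        violations.append(f"expression_tumour: {exc}")
    try:
        normal = io_mod.read_expression(expression_normal)
    except Exception as exc:
        violations.append(f"expression_normal: {exc}")
    try:
        clin = io_mod.read_clinical(clinical)
    except Exception as exc:
        violations.append(f"clinical: {exc}")
    if gmt is not None:
        try:
            io_mod.read_gmt(gmt)
        except Exception as exc:
            violations.append(f"gmt: {exc}")
    if tumour is not None:
        for gene_type in ("lncRNA", "mRNA"):
            if (tumour.gene_types == gene_type).sum() == 0:
                violations.append(f"expression_tumour: no genes of type {gene_type}")
    if tumour is not None and clin is not None:
        missing = [s for s in clin.sample_ids if s not in set(tumour.sample_ids)]
        for s in missing:
            violations.append(f"clinical sample {s} absent from tumour expression")
    if tumour is not None and normal is not None:
        if not tumour.gene_ids.equals(normal.gene_ids):
            violations.append("tumour and normal expression gene ids differ")
    return violations


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    counts: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)

    def add(self, name: str, path: Path) -> None:
        self.artifacts[name] = {"path": path.name, "sha256": _sha256(path)}

    def write(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {"config": self.config, "counts": self.counts, "artifacts": self.artifacts},
                indent=1,
                sort_keys=True,
            )
        )


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage for both orientations and write all artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config))
    counts = manifest.counts

    # --- load & preprocess -------------------------------------------------
    tumour = io_mod.preprocess(io_mod.read_expression(config.expression_tumour))
    normal = io_mod.preprocess(io_mod.read_expression(config.expression_normal))
    normal = normal.subset_genes(
        [g for g in tumour.gene_ids if g in set(normal.gene_ids)]
    )
    clinical = io_mod.read_clinical(config.clinical)
    counts["n_lnc"] = int(len(tumour.lnc_ids))
    counts["n_mrna"] = int(len(tumour.mrna_ids))
    counts["n_tumour_samples"] = int(len(tumour.sample_ids))
    path = out / "expression_preprocessed.tsv"
    io_mod.write_expression(tumour, path)
    manifest.add("expression_preprocessed", path)

    # --- correlation -------------------------------------------------------
    cmat, mr_pos, mr_neg, sets = corr.correlated_sets_from_expression(
        tumour, config.mr_fraction
    )
    counts["mr_cutoff"] = sets.cutoff
    counts["mean_pos_set_size"] = float(
        pd.Series({k: len(v) for k, v in sets.pos_sets.items()}).mean()
    )
    path = out / "correlated_sets.json"
    path.write_text(
        json.dumps(
            {
                "cutoff": sets.cutoff,
                "positive": {k: sorted(v) for k, v in sorted(sets.pos_sets.items())},
                "negative": {k: sorted(v) for k, v in sorted(sets.neg_sets.items())},
            },
            indent=1,
            sort_keys=True,
        )
    )
    manifest.add("correlated_sets", path)

    # --- association + network, per orientation ---------------------------
    n_universe = len(tumour.mrna_ids)
    all_modules: list[net.Module] = []
    pcc_tables: dict[str, pd.DataFrame] = {}
    for orientation in ("positive", "negative"):
        edges = assoc.build_edge_list(
            sets, orientation, config.pcc_threshold, n_universe
        )
        path = out / f"edges_{orientation}.tsv"
        assoc.write_edge_list(edges, path)
        manifest.add(f"edges_{orientation}", path)
        counts[f"n_edges_{orientation}"] = len(edges)

        graph = net.build_network(edges)
        modules = net.extract_modules(graph, config.min_module_size, orientation)
        all_modules.extend(modules)
        counts[f"n_modules_{orientation}"] = len(modules)
        pcc_tables[orientation] = assoc.association_matrix(sets, orientation, n_universe)

        if graph.number_of_nodes():
            path = out / f"network_{orientation}.graphml"
            net.write_graphml(graph, path)
            manifest.add(f"network_{orientation}", path)
            k, pk = net.degree_density(graph)
            topo = {"k": k.tolist(), "pk": pk.tolist()}
            try:
                fit = net.power_law_fit(k, pk)
                topo.update(
                    slope=fit.slope, intercept=fit.intercept,
                    p_value=fit.p_value, r_squared=fit.r_squared,
                )
            except Exception as exc:
                topo["fit_error"] = str(exc)
            path = out / f"topology_{orientation}.json"
            path.write_text(json.dumps(topo, indent=1, sort_keys=True))
            manifest.add(f"topology_{orientation}", path)
            path = out / f"node_metrics_{orientation}.tsv"
            net.node_metrics(graph, modules).to_csv(path, sep="\t")
            manifest.add(f"node_metrics_{orientation}", path)

    path = out / "modules.tsv"
    net.write_module_table(all_modules, path)
    manifest.add("modules", path)
    counts["n_modules"] = len(all_modules)

    # --- survival screen + signatures --------------------------------------
    thresholds = surv.ScreenThresholds(*config.alphas)
    screen = surv.screen_lncrnas(tumour, normal, clinical, all_modules, thresholds)
    path = out / "screening.tsv"
    surv.write_screen_table(screen, path)
    manifest.add("screening", path)
    counts["n_screened"] = len(screen)
    counts["n_prognostic_lncrnas"] = sum(r.passed for r in screen)

    module_sigs: list[surv.SignatureResult] = []
    summaries = []
    for module in all_modules:
        sig = surv.module_signature(tumour, clinical, module, screen, config.eval_days)
        if sig is None:
            continue
        module_sigs.append(sig)
        summaries.append(surv.signature_summary(sig))
        path = out / f"signature_{sig.signature_id}.tsv"
        surv.write_signature_table(sig, path)
        manifest.add(f"signature_{sig.signature_id}", path)
    counts["n_prognostic_modules"] = len(module_sigs)

    if len(module_sigs) >= 2:
        pooled = surv.pooled_signature(tumour, clinical, module_sigs, config.eval_days)
        summaries.append(surv.signature_summary(pooled))
        path = out / "signature_pooled.tsv"
        surv.write_signature_table(pooled, path)
        manifest.add("signature_pooled", path)
    path = out / "signatures_summary.json"
    path.write_text(json.dumps(summaries, indent=1, sort_keys=True))
    manifest.add("signatures_summary", path)

    # --- enrichment ---------------------------------------------------------
    prognostic_ids = {s.signature_id for s in module_sigs}
    if config.gmt is not None:
        gene_sets = io_mod.read_gmt(config.gmt)
        mr_by_orientation = {"positive": mr_neg, "negative": mr_pos}  # flipped ranks
        for module in all_modules:
            if module.module_id not in prognostic_ids:
                continue
            ranked = enr.module_rank(mr_by_orientation[module.orientation], module)
            results = enr.gsea_preranked(
                ranked,
                gene_sets,
                n_perm=config.n_perm,
                min_size=config.gsea_min_size,
                max_size=config.gsea_max_size,
                seed=config.seed,
            )
            path = out / f"enrichment_{module.module_id}.tsv"
            enr.write_enrichment_table(results, path)
            manifest.add(f"enrichment_{module.module_id}", path)

    manifest.write(out / "manifest.json")
    logger.info("pipeline complete: %s", json.dumps(counts, sort_keys=True))
    return manifest
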