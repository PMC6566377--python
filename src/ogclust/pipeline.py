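"""End-to-end pipeline: simulate -> filter -> cluster -> classify -> annotate -> enrich.

``run_all`` executes the stages in order on one output directory, writing
every intermediate artifact plus a JSON manifest (config hash, seed, per-stage
row counts and wall times). Identical (config, seed) produces byte-identical
analysis artifacts; only the manifest's timings differ between runs.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Dict, List, Optional

import yaml

from . import annotate as ann_mod
from . import enrich as enrich_mod
from . import hits as hits_mod
from . import phyletic as phy_mod
from .mcl import build_similarity_graph, mcl, retain_multispecies, write_groups
from .errors import ConfigError
from .ontology import parse_go_map, parse_obo
from .phyletic import GROUP_LABELS, SpeciesTaxonomy
from .synthetic import SimConfig, simulate_cohort


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: bool = True
    # input paths (required when the simulate stage is disabled)
    hits_path: Optional[str] = None
    taxonomy_path: Optional[str] = None
    obo_path: Optional[str] = None
    refmap_path: Optional[str] = None
    go_hits_path: Optional[str] = None
    # synthetic-cohort knobs (flat overrides of SimConfig defaults)
    n_families: int = 300
    planted_group: str = "Cha+Emb"
    p_planted: float = 0.4
    p_background: float = 0.05
    # stage thresholds
    max_evalue_cluster: float = 1e-5
    min_qcov: float = 0.5
    max_evalue_go: float = 1e-10
    max_evalue_domain: float = 1e-15
    min_hmm_cov: float = 0.8
    inflation: float = 1.5
    go_level: int = 6
    alpha: float = 0.05
    adjust_method: str = "holm"
    alternative: str = "greater"
    top_n: int = 20
    control_group: str = "Chl+Cha+Emb"

    def validate(self) -> None:
        if self.inflation <= 1:
            raise ConfigError(f"inflation must exceed 1, got {self.inflation}")
        if not (0 < self.alpha <= 1):
            raise ConfigError(f"alpha must lie in (0, 1], got {self.alpha}")
        for key in ("max_evalue_cluster", "max_evalue_go", "max_evalue_domain"):
            v = getattr(self, key)
            if v <= 0:
                raise ConfigError(f"{key} must be positive, got {v}")
        for key in ("min_qcov", "min_hmm_cov", "p_planted", "p_background"):
            v = getattr(self, key)
            if not (0 <= v <= 1):
                raise ConfigError(f"{key} must lie in [0, 1], got {v}")
        if self.control_group not in GROUP_LABELS:
            raise ConfigError(f"control_group {self.control_group!r} is not a group label")
        if self.adjust_method not in ("holm", "bh", "BH"):
            raise ConfigError(f"adjust_method must be 'holm' or 'bh', got {self.adjust_method!r}")
        if self.alternative not in ("greater", "two-sided"):
            raise ConfigError(f"alternative must be 'greater' or 'two-sided'")
        if self.go_level < 1 or self.top_n < 0 or self.n_families < 0:
            raise ConfigError("go_level must be >= 1; top_n and n_families >= 0")
        if not self.simulate:
            for key in ("hits_path", "taxonomy_path", "obo_path", "refmap_path", "go_hits_path"):
                if getattr(self, key) is None:
                    raise ConfigError(f"simulate disabled but {key} missing")

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n_families=self.n_families,
            planted_group=self.planted_group,
            p_planted=self.p_planted,
            p_background=self.p_background,
            seed=self.seed,
        )

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def validate_config(raw_text: str) -> PipelineConfig:
    """Parse a YAML config into a range-checked :class:`PipelineConfig`.

    Unknown keys are errors, with a closest-match suggestion.
    """
    data = yaml.safe_load(raw_text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config must be a YAML mapping")
    known = {f.name for f in fields(PipelineConfig)}
    for key in data:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown config key {key!r}{suffix}")
    try:
        config = PipelineConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from None
    config.validate()
    return config


def run_all(config: PipelineConfig, outdir) -> Dict[str, Any]:
    """Run every stage; returns the manifest (also written to manifest.json)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: List[Dict[str, Any]] = []

    def record(name: str, t0: float, rows_in: int, rows_out: int) -> None:
        stages.append(
            {
                "stage": name,
                "rows_in": rows_in,
                "rows_out": rows_out,
                "seconds": round(time.perf_counter() - t0, 3),
            }
        )

    # -- simulate ----------------------------------------------------------
    if config.simulate:
        t0 = time.perf_counter()
        truth = simulate_cohort(config.sim_config(), outdir)
        record("simulate", t0, 0, len(truth.protein_family))
        hits_path = outdir / "hits.tsv"
        taxonomy_path = outdir / "species.tsv"
        obo_path = outdir / "go.obo"
        refmap_path = outdir / "refmap.tsv"
        go_hits_path = outdir / "gohits.tsv"
        protein_species = truth.protein_species
    else:
        for key in ("hits_path", "taxonomy_path", "obo_path", "refmap_path", "go_hits_path"):
            p = getattr(config, key)
            if not Path(p).exists():
                raise ConfigError(f"missing input for {key}: {p}")
        hits_path, taxonomy_path = config.hits_path, config.taxonomy_path
        obo_path, refmap_path = config.obo_path, config.refmap_path
        go_hits_path = config.go_hits_path
        protein_species = None

    taxonomy = SpeciesTaxonomy.from_tsv(taxonomy_path)

    # -- filter ------------------------------------------------------------
    t0 = time.perf_counter()
    raw_hits = list(hits_mod.parse_hit_table(hits_path))
    filtered = hits_mod.filter_hits(
        raw_hits, max_evalue=config.max_evalue_cluster, min_query_cov=config.min_qcov
    )
    hits_mod.write_hit_table(filtered, outdir / "hits.filtered.tsv")
    record("filter", t0, len(raw_hits), len(filtered))

    # -- cluster -----------------------------------------------------------
    t0 = time.perf_counter()
    if protein_species is None:
        # protein universe = every id in the hit table; species taken from
        # the middle field of the <family>.<species>.<k> id convention
        protein_species = {}
        for h in raw_hits:
            for p in (h.query_id, h.subject_id):
                sp = p.split(".")[1] if "." in p else p
                protein_species[p] = sp
    graph = build_similarity_graph(filtered, protein_species)
    clusters = mcl(graph, inflation=config.inflation)
    ogcs, excluded = retain_multispecies(clusters)
    write_groups(ogcs, outdir / "groups.txt")
    record("cluster", t0, graph.number_of_nodes(), len(ogcs))

    # -- classify ----------------------------------------------------------
    t0 = time.perf_counter()
    table, _ = phy_mod.tabulate_groups(ogcs, taxonomy)
    table.to_tsv(outdir / "group_table.tsv")
    venn = phy_mod.venn_counts(table)
    (outdir / "venn.tsv").write_text(
        "\n".join(f"{k}\t{v}" for k, v in venn.items()) + "\n"
    )
    occ = phy_mod.species_occupancy(ogcs, taxonomy)
    phy_mod.write_occupancy_tsv(occ, outdir / "occupancy.tsv")
    record("classify", t0, len(ogcs), table.total_ogcs)

    # -- annotate ----------------------------------------------------------
    t0 = time.perf_counter()
    dag = parse_obo(str(obo_path))
    ref_map = parse_go_map(refmap_path)
    go_hits = list(hits_mod.parse_hit_table(go_hits_path))
    annotation = ann_mod.transfer_annotations(go_hits, ref_map, config.max_evalue_go)
    ann_mod.write_annotations(annotation, outdir / "annotations.tsv")

    proteins_by_group: Dict[str, List[str]] = {g: [] for g in GROUP_LABELS}
    for ogc in ogcs:
        group = phy_mod.classify_ogc(ogc.species_set, taxonomy)
        proteins_by_group[group].extend(sorted(ogc.members))
    rates = ann_mod.annotation_rates(annotation, proteins_by_group)
    ann_mod.write_rates(rates, outdir / "annotation_rates.tsv")
    record("annotate", t0, len(go_hits), len(annotation))

    # -- enrich ------------------------------------------------------------
    t0 = time.perf_counter()
    control = enrich_mod.count_terms(
        annotation,
        proteins_by_group[config.control_group],
        dag,
        level=config.go_level,
        group=config.control_group,
    )
    all_results = []
    top_lines = ["group\tterm_id\tterm_name\tp_adj\tminus_log10_p_adj"]
    for group in GROUP_LABELS:
        if group == config.control_group or not proteins_by_group[group]:
            continue
        tested = enrich_mod.count_terms(
            annotation, proteins_by_group[group], dag,
            level=config.go_level, group=group,
        )
        if tested.n == 0:
            continue
        results = enrich_mod.enrich_group(
            tested, control,
            alpha=config.alpha, method=config.adjust_method,
            alternative=config.alternative,
        )
        all_results.extend(results)
        report = enrich_mod.top_report(results, config.top_n)
        for r, mlp in zip(report.rows, report.minus_log10_padj()):
            top_lines.append(
                f"{group}\t{r.term_id}\t{dag.name(r.term_id)}\t{r.p_adj:.6g}\t{mlp:.4f}"
            )
    enrich_mod.write_enrichment(all_results, outdir / "enrichment.tsv", dag)
    (outdir / "top_terms.tsv").write_text("\n".join(top_lines) + "\n")
    record("enrich", t0, len(all_results), sum(1 for r in all_results if r.significant))

    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "excluded_proteins": excluded,
        "clustered_proteins": sum(len(c.members) for c in ogcs),
        "stages": stages,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
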