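"""Synthetic comparative-genomics cohort with known ground truth.

The generator emulates the inputs of a 14-proteome plant/algal comparison:
a species panel over the four clades (Chl, KCM, ZCC, Emb), gene families
with clade-structured presence/absence drawn from the nine phyletic-group
rules, an all-vs-all similarity hit table (strong within-family blocks plus
cross-family decoys that violate the filtering thresholds), a small rooted
tree ontology, and a reference protein -> GO mapping with a term planted at
elevated frequency in one chosen group. Every downstream stage (filter,
cluster, classify, annotate, enrich) is therefore testable against a known
answer.

No sequence-level evolution is simulated: hit E-values, coverages and GO
assignments are drawn directly from the configured distributions. One RNG
stream per output artifact is derived from the master seed by fixed labels,
so regenerating one artifact never perturbs the others.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterator, List, Mapping, Optional, Set, Tuple

import numpy as np

from .errors import ConfigError
from .hits import SimilarityHit, write_hit_table
from .ontology import GODag, parse_obo, write_go_map
from .phyletic import GROUP_LABELS, SpeciesTaxonomy, classify_ogc

#: Default group mixture: the nine-group OGC proportions observed in the
#: 14-species study this cohort emulates (out of 25,485 clusters).
DEFAULT_GROUP_MIXTURE: Dict[str, float] = {
    "Chl+Cha+Emb": 5031 / 25485,
    "Cha+Emb": 4174 / 25485,
    "Chl+Cha": 1221 / 25485,
    "Chl+Emb": 140 / 25485,
    "Emb": 4849 / 25485,
    "Cha": 3600 / 25485,
    "ZCC": 3807 / 25485,
    "KCM": 66 / 25485,
    "Chl": 2597 / 25485,
}

_STREAMS = {"families": 0, "hits": 1, "goref": 2}


def _rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[label],)))


@dataclass
class SimConfig:
    n_species_per_clade: Dict[str, int] = field(
        default_factory=lambda: {"Chl": 2, "KCM": 2, "ZCC": 5, "Emb": 5}
    )
    n_families: int = 300
    group_mixture: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_MIXTURE)
    )
    proteins_per_family_per_species: Tuple[int, int] = (1, 2)
    within_family_evalue_range: Tuple[float, float] = (1e-180, 1e-20)
    decoy_evalue_range: Tuple[float, float] = (1e-4, 1.0)
    decoy_coverage_range: Tuple[float, float] = (0.05, 0.45)
    decoys_per_family: float = 2.0
    obo_depth: int = 6
    obo_branching: int = 2
    planted_term: Optional[str] = None
    planted_group: str = "Cha+Emb"
    p_planted: float = 0.4
    p_background: float = 0.05
    background_terms_per_reference: Tuple[int, int] = (1, 3)
    seed: int = 0

    def validate(self) -> None:
        if self.n_families < 0:
            raise ConfigError("n_families must be >= 0")
        mix_sum = sum(self.group_mixture.values())
        if abs(mix_sum - 1.0) > 1e-9:
            raise ConfigError(f"group_mixture must sum to 1, got {mix_sum}")
        for g, p in self.group_mixture.items():
            if g not in GROUP_LABELS:
                raise ConfigError(f"unknown group label in mixture: {g!r}")
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"mixture probability out of [0,1] for {g!r}")
        for p in (self.p_planted, self.p_background):
            if not (0.0 <= p <= 1.0):
                raise ConfigError("planted/background probabilities must be in [0,1]")
        if self.p_planted < self.p_background:
            raise ConfigError("p_planted must be >= p_background")
        lo, hi = self.proteins_per_family_per_species
        if lo < 1 or hi < lo:
            raise ConfigError("proteins_per_family_per_species must satisfy 1 <= lo <= hi")
        if self.planted_group not in GROUP_LABELS:
            raise ConfigError(f"unknown planted_group {self.planted_group!r}")


@dataclass
class GroundTruth:
    """Generator-side truth: family composition and planted-signal bookkeeping."""

    families: Dict[str, Tuple[str, FrozenSet[str]]]  # fid -> (group, species)
    protein_family: Dict[str, str]
    protein_species: Dict[str, str]
    protein_length: Dict[str, int]
    planted_term: Optional[str] = None
    planted_group: str = "Cha+Emb"
    planted_assignments: Dict[str, bool] = field(default_factory=dict)

    @property
    def partition(self) -> Set[FrozenSet[str]]:
        by_family: Dict[str, Set[str]] = {}
        for p, f in self.protein_family.items():
            by_family.setdefault(f, set()).add(p)
        return {frozenset(v) for v in by_family.values()}

    def group_of_protein(self, protein: str) -> str:
        return self.families[self.protein_family[protein]][0]

    def to_json(self, path) -> None:
        payload = {
            "families": {
                f: [g, sorted(sp)] for f, (g, sp) in sorted(self.families.items())
            },
            "protein_family": self.protein_family,
            "protein_species": self.protein_species,
            "protein_length": self.protein_length,
            "planted_term": self.planted_term,
            "planted_group": self.planted_group,
            "planted_assignments": self.planted_assignments,
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            families={f: (g, frozenset(sp)) for f, (g, sp) in d["families"].items()},
            protein_family=d["protein_family"],
            protein_species=d["protein_species"],
            protein_length={k: int(v) for k, v in d["protein_length"].items()},
            planted_term=d["planted_term"],
            planted_group=d["planted_group"],
            planted_assignments=d["planted_assignments"],
        )


# ------------------------------------------------------------------ species
#: Feasibility requirements per group: clades needing >=1 (or >=2) species.
_GROUP_NEEDS: Dict[str, List[Tuple[Tuple[str, ...], int]]] = {
    "Chl+Cha+Emb": [(("Chl",), 1), (("KCM", "ZCC"), 1), (("Emb",), 1)],
    "Cha+Emb": [(("KCM", "ZCC"), 1), (("Emb",), 1)],
    "Chl+Cha": [(("Chl",), 1), (("KCM", "ZCC"), 1)],
    "Chl+Emb": [(("Chl",), 1), (("Emb",), 1)],
    "Emb": [(("Emb",), 2)],
    "Cha": [(("KCM",), 1), (("ZCC",), 1)],
    "ZCC": [(("ZCC",), 2)],
    "KCM": [(("KCM",), 2)],
    "Chl": [(("Chl",), 2)],
}


def make_species_panel(config: SimConfig) -> SpeciesTaxonomy:
    """Mint the species panel: ``<clade><i>`` identifiers per configured clade.

    Raises a configuration error when a group with positive mixture weight
    cannot be realized by the panel (e.g. a two-species single-clade group
    over a clade with fewer than two species).
    """
    counts = config.n_species_per_clade
    for clade, n in counts.items():
        if clade not in ("Chl", "KCM", "ZCC", "Emb"):
            raise ConfigError(f"unknown clade {clade!r}")
        if n < 0:
            raise ConfigError(f"negative species count for clade {clade}")
    for group, prob in config.group_mixture.items():
        if prob <= 0:
            continue
        for clades, need in _GROUP_NEEDS[group]:
            have = sum(counts.get(c, 0) for c in clades)
            if have < need:
                raise ConfigError(
                    f"group {group!r} needs >= {need} species in {'/'.join(clades)}, "
                    f"panel has {have}"
                )
    mapping = {}
    for clade in ("Chl", "KCM", "ZCC", "Emb"):
        for i in range(1, counts.get(clade, 0) + 1):
            mapping[f"{clade}{i}"] = clade
    return SpeciesTaxonomy(mapping)


#: Clades whose species may appear at all in a family of each group.
_GROUP_ALLOWED: Dict[str, Tuple[str, ...]] = {
    "Chl+Cha+Emb": ("Chl", "KCM", "ZCC", "Emb"),
    "Cha+Emb": ("KCM", "ZCC", "Emb"),
    "Chl+Cha": ("Chl", "KCM", "ZCC"),
    "Chl+Emb": ("Chl", "Emb"),
    "Emb": ("Emb",),
    "Cha": ("KCM", "ZCC"),
    "ZCC": ("ZCC",),
    "KCM": ("KCM",),
    "Chl": ("Chl",),
}


def _satisfies(group: str, present: Set[str], taxonomy: SpeciesTaxonomy) -> bool:
    if len(present) < 2:
        return False
    clades = {taxonomy.clade_of(s) for s in present}
    for need_clades, need in _GROUP_NEEDS[group]:
        if sum(1 for s in present if taxonomy.clade_of(s) in need_clades) < need:
            return False
    return clades <= set(_GROUP_ALLOWED[group])


def sample_presence_set(
    group: str, taxonomy: SpeciesTaxonomy, rng: np.random.Generator
) -> FrozenSet[str]:
    """Uniform sample over species sets satisfying the group's rule.

    Rejection sampling over independent Bernoulli(0.5) presence draws,
    restricted to the clades the rule allows (species of forbidden clades
    carry zero mass under the rule, so the restriction is exact).
    """
    allowed = sorted(
        s for s in taxonomy if taxonomy.clade_of(s) in _GROUP_ALLOWED[group]
    )
    while True:
        mask = rng.random(len(allowed)) < 0.5
        present = {s for s, m in zip(allowed, mask) if m}
        if _satisfies(group, present, taxonomy):
            return frozenset(present)


def sample_families(
    taxonomy: SpeciesTaxonomy, config: SimConfig, rng: Optional[np.random.Generator] = None
) -> GroundTruth:
    """Draw the family ground truth: per family a group label from the
    mixture, a rule-satisfying species presence set, and minted proteins."""
    config.validate()
    if rng is None:
        rng = _rng(config.seed, "families")
    labels = sorted(config.group_mixture)
    probs = np.array([config.group_mixture[g] for g in labels])
    probs = probs / probs.sum()
    lo, hi = config.proteins_per_family_per_species

    truth = GroundTruth(
        families={},
        protein_family={},
        protein_species={},
        protein_length={},
        planted_group=config.planted_group,
    )
    for i in range(config.n_families):
        fid = f"F{i:04d}"
        group = labels[rng.choice(len(labels), p=probs)]
        present = sample_presence_set(group, taxonomy, rng)
        truth.families[fid] = (group, present)
        for sp in sorted(present):
            for k in range(1, int(rng.integers(lo, hi + 1)) + 1):
                pid = f"{fid}.{sp}.{k}"
                truth.protein_family[pid] = fid
                truth.protein_species[pid] = sp
                truth.protein_length[pid] = int(rng.integers(200, 1201))
    return truth


# --------------------------------------------------------------------- hits
def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(10 ** rng.uniform(math.log10(lo), math.log10(hi)))


def _make_hit(
    q: str,
    s: str,
    qlen: int,
    slen: int,
    evalue: float,
    coverage: float,
    rng: np.random.Generator,
) -> SimilarityHit:
    qend = max(1, int(coverage * qlen))
    alen = qend
    pident = round(float(rng.uniform(30.0, 95.0)), 1)
    return SimilarityHit(
        query_id=q,
        subject_id=s,
        percent_identity=pident,
        alignment_length=alen,
        mismatches=int(alen * (1 - pident / 100) * 0.8),
        gap_opens=int(rng.integers(0, 3)),
        qstart=1,
        qend=qend,
        sstart=1,
        send=min(alen, slen),
        evalue=evalue,
        bitscore=round(alen * float(rng.uniform(0.8, 2.0)), 1),
        qlen=qlen,
        slen=slen,
    )


def emit_hit_table(
    truth: GroundTruth, config: SimConfig, rng: Optional[np.random.Generator] = None
) -> Iterator[SimilarityHit]:
    """Yield the all-vs-all hit rows for the cohort.

    Every ordered intra-family pair gets a hit passing the clustering
    filters (E in the within-family range, query coverage > 0.5); self-hits
    are emitted as real search output would contain them; decoy inter-family
    hits violate the E-value threshold, the coverage threshold, or both.
    """
    if rng is None:
        rng = _rng(config.seed, "hits")
    e_lo, e_hi = config.within_family_evalue_range
    d_lo, d_hi = config.decoy_evalue_range
    c_lo, c_hi = config.decoy_coverage_range

    by_family: Dict[str, List[str]] = {}
    for p, f in truth.protein_family.items():
        by_family.setdefault(f, []).append(p)

    for fid in sorted(by_family):
        members = sorted(by_family[fid])
        for q in members:  # self-hits: perfect full-length matches
            L = truth.protein_length[q]
            yield SimilarityHit(q, q, 100.0, L, 0, 0, 1, L, 1, L, 0.0, 2.0 * L, L, L)
        for q in members:
            for s in members:
                if q == s:
                    continue
                yield _make_hit(
                    q,
                    s,
                    truth.protein_length[q],
                    truth.protein_length[s],
                    _log_uniform(rng, e_lo, e_hi),
                    float(rng.uniform(0.55, 0.95)),
                    rng,
                )

    fids = sorted(by_family)
    if len(fids) >= 2:
        n_decoys = int(round(config.decoys_per_family * len(fids)))
        for _ in range(n_decoys):
            fa, fb = rng.choice(len(fids), size=2, replace=False)
            q = by_family[fids[fa]][int(rng.integers(len(by_family[fids[fa]])))]
            s = by_family[fids[fb]][int(rng.integers(len(by_family[fids[fb]])))]
            mode = int(rng.integers(3))  # 0: bad E, 1: bad coverage, 2: both
            if mode == 0:
                evalue, cov = _log_uniform(rng, d_lo, d_hi), float(rng.uniform(0.55, 0.95))
            elif mode == 1:
                evalue, cov = _log_uniform(rng, e_lo, e_hi), float(rng.uniform(c_lo, c_hi))
            else:
                evalue, cov = _log_uniform(rng, d_lo, d_hi), float(rng.uniform(c_lo, c_hi))
            yield _make_hit(
                q, s, truth.protein_length[q], truth.protein_length[s], evalue, cov, rng
            )


# ---------------------------------------------------------------- ontology
_NAMESPACE_PREFIX = {
    "biological_process": "bp",
    "molecular_function": "mf",
    "cellular_component": "cc",
}


def make_obo(
    depth: int,
    branching: int,
    namespaces: Tuple[str, ...] = ("biological_process",),
) -> str:
    """Synthesize a rooted full-tree ontology (OBO 1.2 text) per namespace.

    A term at tree depth d has level d (root = level 1); a single namespace
    of depth 6 / branching 2 yields 63 terms, 32 of them at level 6.
    """
    if depth < 1 or branching < 1:
        raise ConfigError("depth and branching must be >= 1")
    stanzas = ["format-version: 1.2", "ontology: synthetic-go", ""]
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"GO:{counter:07d}"

    for ns in namespaces:
        prefix = _NAMESPACE_PREFIX.get(ns, ns[:2])
        root = new_id()
        stanzas += [
            "[Term]",
            f"id: {root}",
            f"name: {prefix} root",
            f"namespace: {ns}",
            "",
        ]
        frontier = [root]
        for level in range(2, depth + 1):
            nxt = []
            for parent in frontier:
                for _ in range(branching):
                    tid = new_id()
                    stanzas += [
                        "[Term]",
                        f"id: {tid}",
                        f"name: {prefix} term {tid[3:]} (level {level})",
                        f"namespace: {ns}",
                        f"is_a: {parent}",
                        "",
                    ]
                    nxt.append(tid)
            frontier = nxt
    return "\n".join(stanzas)


# ------------------------------------------------------------ GO reference
def make_go_reference(
    truth: GroundTruth,
    dag: GODag,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Dict[str, Set[str]], List[SimilarityHit]]:
    """Create the reference GO map and query->reference hit rows.

    Each query protein gets one reference hit with E < 1e-10. References of
    planted-group proteins carry the planted term with probability
    ``p_planted``; all others with ``p_background``. Background terms are
    drawn uniformly from the non-root, non-planted terms of the DAG.
    Assignment events are recorded in ``truth.planted_assignments``.
    """
    if rng is None:
        rng = _rng(config.seed, "goref")
    planted = config.planted_term
    if planted is None:
        level6 = dag.terms_at_level(6)
        candidates = level6 if level6 else dag.terms_at_level(max(dag.levels().values()))
        planted = candidates[0]
    if planted not in dag:
        raise ConfigError(f"planted term {planted!r} absent from the ontology")
    truth.planted_term = planted

    roots = set(dag.roots.values())
    pool = sorted(t for t in dag.terms if t not in roots and t != planted)
    lo, hi = config.background_terms_per_reference

    ref_map: Dict[str, Set[str]] = {}
    hit_rows: List[SimilarityHit] = []
    for protein in sorted(truth.protein_family):
        ref = f"REF_{protein}"
        n_bg = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(pool), size=min(n_bg, len(pool)), replace=False)
        terms = {pool[i] for i in idx}
        group = truth.group_of_protein(protein)
        p = config.p_planted if group == config.planted_group else config.p_background
        carries = bool(rng.random() < p)
        if carries:
            terms.add(planted)
        truth.planted_assignments[protein] = carries
        ref_map[ref] = terms
        L = truth.protein_length[protein]
        hit_rows.append(
            SimilarityHit(
                protein, ref, round(float(rng.uniform(60.0, 99.0)), 1), L, 0, 0,
                1, L, 1, L, _log_uniform(rng, 1e-100, 1e-12),
                round(2.0 * L, 1), L, L,
            )
        )
    return ref_map, hit_rows


# ------------------------------------------------------------- orchestration
def simulate_cohort(config: SimConfig, outdir) -> GroundTruth:
    """Generate and write the full cohort to ``outdir``.

    Writes: species.tsv, hits.tsv, go.obo, refmap.tsv, gohits.tsv,
    truth.json. Byte-identical for equal (config, seed).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    taxonomy = make_species_panel(config)
    taxonomy.to_tsv(outdir / "species.tsv")

    truth = sample_families(taxonomy, config)
    write_hit_table(emit_hit_table(truth, config), outdir / "hits.tsv")

    obo_text = make_obo(config.obo_depth, config.obo_branching)
    (outdir / "go.obo").write_text(obo_text)

    dag = parse_obo(str(outdir / "go.obo"))
    ref_map, go_hits = make_go_reference(truth, dag, config)
    write_go_map(ref_map, outdir / "refmap.tsv")
    write_hit_table(go_hits, outdir / "gohits.tsv")

    truth.to_json(outdir / "truth.json")
    return truth
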