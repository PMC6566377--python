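"""The synthetic cohort generator: panel, families, hits, GO reference."""

import io

import numpy as np
import pytest

from ogclust import (
    ConfigError,
    SimConfig,
    classify_ogc,
    filter_hits,
    make_obo,
    make_species_panel,
    parse_obo,
    sample_families,
    simulate_cohort,
    transfer_annotations,
)
from ogclust.synthetic import GroundTruth, emit_hit_table, make_go_reference


class TestSpeciesPanel:
    def test_default_panel_is_fourteen_species(self, default_taxonomy):
        assert len(default_taxonomy) == 14
        for clade, n in [("Chl", 2), ("KCM", 2), ("ZCC", 5), ("Emb", 5)]:
            assert len(default_taxonomy.species_in(clade)) == n

    def test_minimal_panel(self):
        cfg = SimConfig(
            n_species_per_clade={"Chl": 1, "KCM": 1, "ZCC": 1, "Emb": 1},
            group_mixture={"Chl+Cha+Emb": 1.0},
        )
        assert len(make_species_panel(cfg)) == 4

    def test_infeasible_group_is_config_error(self):
        cfg = SimConfig(
            n_species_per_clade={"Chl": 0, "KCM": 2, "ZCC": 5, "Emb": 5},
        )  # default mixture includes Chl-containing groups
        with pytest.raises(ConfigError, match="Chl"):
            make_species_panel(cfg)

    def test_single_clade_group_needs_two_species(self):
        cfg = SimConfig(
            n_species_per_clade={"Chl": 2, "KCM": 1, "ZCC": 5, "Emb": 5},
            group_mixture={"KCM": 1.0},
        )
        with pytest.raises(ConfigError):
            make_species_panel(cfg)


class TestSampleFamilies:
    def test_every_family_classifies_to_its_intended_group(
        self, default_taxonomy
    ):
        for seed in range(3):
            truth = sample_families(
                default_taxonomy, SimConfig(n_families=50, seed=seed)
            )
            for fid, (group, species) in truth.families.items():
                assert classify_ogc(species, default_taxonomy) == group, fid

    def test_zero_families(self, default_taxonomy):
        truth = sample_families(default_taxonomy, SimConfig(n_families=0))
        assert truth.families == {} and truth.protein_family == {}

    def test_mixture_must_sum_to_one(self, default_taxonomy):
        cfg = SimConfig(group_mixture={"Emb": 0.5})
        with pytest.raises(ConfigError, match="sum"):
            sample_families(default_taxonomy, cfg)

    def test_planted_probabilities_ordered(self):
        with pytest.raises(ConfigError):
            SimConfig(p_planted=0.1, p_background=0.4).validate()


def single_family_truth(n_proteins=3):
    proteins = {f"F0000.Emb{i}.1": f"Emb{i}" for i in range(1, n_proteins + 1)}
    return GroundTruth(
        families={"F0000": ("Emb", frozenset(proteins.values()))},
        protein_family={p: "F0000" for p in proteins},
        protein_species=dict(proteins),
        protein_length={p: 300 for p in proteins},
    )


class TestHitTable:
    def test_three_protein_family_emits_six_directed_plus_self_hits(self):
        truth = single_family_truth(3)
        rows = list(emit_hit_table(truth, SimConfig(seed=1)))
        directed = [h for h in rows if h.query_id != h.subject_id]
        selfs = [h for h in rows if h.query_id == h.subject_id]
        assert len(directed) == 6 and len(selfs) == 3

    def test_intra_family_hits_pass_filters_and_decoys_fail(self, default_taxonomy):
        cfg = SimConfig(n_families=15, seed=4)
        truth = sample_families(default_taxonomy, cfg)
        rows = list(emit_hit_table(truth, cfg))
        kept = filter_hits(rows)
        same_family = lambda h: (
            truth.protein_family[h.query_id] == truth.protein_family[h.subject_id]
        )
        assert all(same_family(h) for h in kept)
        n_intra_pairs = sum(
            1 for h in rows if h.query_id != h.subject_id and same_family(h)
        )
        assert len(kept) == n_intra_pairs  # every non-self intra-family row survives

    def test_deterministic_given_seed(self, tmp_path):
        out_a, out_b = tmp_path / "a", tmp_path / "b"
        cfg = SimConfig(n_families=10, seed=21)
        simulate_cohort(cfg, out_a)
        simulate_cohort(cfg, out_b)
        for name in ("hits.tsv", "species.tsv", "go.obo", "refmap.tsv",
                     "gohits.tsv", "truth.json"):
            assert (out_a / name).read_bytes() == (out_b / name).read_bytes(), name


class TestGOReference:
    def _setup(self, p_planted, p_background, default_taxonomy, seed=8):
        cfg = SimConfig(
            n_families=30, seed=seed, p_planted=p_planted, p_background=p_background
        )
        truth = sample_families(default_taxonomy, cfg)
        dag = parse_obo(io.StringIO(make_obo(6, 2)))
        ref_map, hits = make_go_reference(truth, dag, cfg)
        return cfg, truth, dag, ref_map, hits

    def test_deterministic_limits(self, default_taxonomy):
        cfg, truth, dag, ref_map, hits = self._setup(1.0, 0.0, default_taxonomy)
        ann = transfer_annotations(hits, ref_map)
        planted = truth.planted_term
        in_group = [
            p for p in truth.protein_family
            if truth.group_of_protein(p) == cfg.planted_group
        ]
        outside = [p for p in truth.protein_family if p not in set(in_group)]
        assert all(planted in ann.terms[p] for p in in_group)
        assert not any(planted in ann.terms.get(p, set()) for p in outside)

    def test_every_query_gets_reference_hit_below_cutoff(self, default_taxonomy):
        _, truth, _, _, hits = self._setup(0.4, 0.05, default_taxonomy)
        queried = {h.query_id for h in hits}
        assert queried == set(truth.protein_family)
        assert all(h.evalue < 1e-10 for h in hits)

    def test_planted_term_defaults_to_level_six(self, default_taxonomy):
        _, truth, dag, _, _ = self._setup(0.4, 0.05, default_taxonomy)
        assert dag.levels()[truth.planted_term] == 6

    def test_no_planted_signal_is_rarely_called_significant(self, default_taxonomy):
        """With p_planted == p_background the planted term must come out
        non-significant (Holm, alpha 0.05) in at least 90% of seeds."""
        from ogclust.enrich import count_terms, enrich_group
        from ogclust.experiment import default_dag
        from ogclust.phyletic import GROUP_LABELS

        dag = default_dag()
        n_sig = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cfg = SimConfig(seed=seed, p_planted=0.05, p_background=0.05)
            truth = sample_families(default_taxonomy, cfg)
            ref_map, hits = make_go_reference(truth, dag, cfg)
            ann = transfer_annotations(hits, ref_map)
            by_group = {g: [] for g in GROUP_LABELS}
            for p in truth.protein_family:
                by_group[truth.group_of_protein(p)].append(p)
            control = count_terms(ann, by_group["Chl+Cha+Emb"], dag)
            tested = count_terms(ann, by_group[cfg.planted_group], dag)
            planted = next(
                (r for r in enrich_group(tested, control)
                 if r.term_id == truth.planted_term),
                None,
            )
            n_sig += bool(planted and planted.significant)
        assert n_sig / n_seeds <= 0.10

    def test_absent_planted_term_is_error(self, default_taxonomy):
        cfg = SimConfig(n_families=5, planted_term="GO:9999999")
        truth = sample_families(default_taxonomy, cfg)
        dag = parse_obo(io.StringIO(make_obo(3, 2)))
        with pytest.raises(ConfigError, match="planted"):
            make_go_reference(truth, dag, cfg)
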