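"""Nine-way phyletic classification and the report aggregations."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ogclust import (
    Cluster,
    OGCTable,
    SpeciesTaxonomy,
    TaxonomyError,
    classify_ogc,
    species_occupancy,
    tabulate_groups,
    venn_counts,
)
from ogclust.phyletic import GROUP_LABELS
from ogclust.published import GO_ANNOTATED_COUNTS, OGC_GROUP_COUNTS

TAX = SpeciesTaxonomy(
    {
        "Cre": "Chl", "Vca": "Chl",
        "Kni": "KCM", "Mvi": "KCM",
        "Spr": "ZCC", "Zcir": "ZCC", "Zygy": "ZCC", "Nmi": "ZCC", "Cor": "ZCC",
        "Ath": "Emb", "Osa": "Emb", "Ppa": "Emb", "Smo": "Emb", "Ptr": "Emb",
    }
)


class TestClassify:
    @pytest.mark.parametrize(
        "species,expected",
        [
            ({"Osa", "Ppa"}, "Emb"),
            ({"Kni", "Zygy"}, "Cha"),
            ({"Cre", "Ath"}, "Chl+Emb"),
            ({"Spr", "Zcir"}, "ZCC"),
            ({"Kni", "Mvi"}, "KCM"),
            ({"Cre", "Vca"}, "Chl"),
            ({"Cre", "Kni", "Ath"}, "Chl+Cha+Emb"),
            ({"Zygy", "Ath"}, "Cha+Emb"),
            ({"Cre", "Spr"}, "Chl+Cha"),
        ],
    )
    def test_rules(self, species, expected):
        assert classify_ogc(species, TAX) == expected

    def test_single_species_rejected(self):
        with pytest.raises(TaxonomyError):
            classify_ogc({"Ath"}, TAX)

    def test_unknown_species_rejected(self):
        with pytest.raises(TaxonomyError):
            classify_ogc({"Ath", "Martian"}, TAX)

    def test_unknown_clade_rejected(self):
        with pytest.raises(TaxonomyError):
            SpeciesTaxonomy({"X": "Chlorophyte"})


def _rule_predicates(species, tax):
    """Independent re-statement of the nine rules, one predicate each."""
    clades = {tax.clade_of(s) for s in species}
    chl, emb = "Chl" in clades, "Emb" in clades
    kcm, zcc = "KCM" in clades, "ZCC" in clades
    cha = kcm or zcc
    return {
        "Chl+Cha+Emb": chl and cha and emb,
        "Cha+Emb": cha and emb and not chl,
        "Chl+Cha": chl and cha and not emb,
        "Chl+Emb": chl and emb and not cha,
        "Emb": clades == {"Emb"},
        "Cha": kcm and zcc and not chl and not emb,
        "ZCC": clades == {"ZCC"},
        "KCM": clades == {"KCM"},
        "Chl": clades == {"Chl"},
    }


@settings(derandomize=True, max_examples=300)
@given(st.sets(st.sampled_from(sorted(TAX)), min_size=2))
def test_exactly_one_rule_fires(species):
    fired = [g for g, ok in _rule_predicates(species, TAX).items() if ok]
    assert len(fired) == 1
    assert classify_ogc(species, TAX) == fired[0]


def _cluster(*species_proteins):
    members, species = [], []
    for sp, n in species_proteins:
        species.append(sp)
        members += [f"{sp}_p{i}" for i in range(n)]
    return Cluster(members=frozenset(members), species_set=frozenset(species))


class TestTabulate:
    def test_single_ogc(self):
        table, _ = tabulate_groups([_cluster(("Ath", 2), ("Osa", 1))], TAX)
        row = table.rows["Emb"]
        assert (row.ogc_count, row.protein_count, row.max_species) == (1, 3, 2)
        assert table.total_ogcs == 1 and table.total_proteins == 3

    def test_empty(self):
        table, _ = tabulate_groups([], TAX)
        assert table.total_ogcs == 0 and table.total_proteins == 0

    def test_published_group_counts_sum_to_totals(self):
        table = OGCTable.from_counts(OGC_GROUP_COUNTS)
        assert table.total_proteins == 270464
        assert table.total_ogcs == 25485

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.sets(st.sampled_from(sorted(TAX)), min_size=2, max_size=6),
            max_size=20,
        )
    )
    def test_conservation(self, species_sets):
        ogcs = [
            _cluster(*((sp, 1) for sp in sset)) for sset in species_sets
        ]
        table, _ = tabulate_groups(ogcs, TAX)
        assert table.total_ogcs == len(ogcs)
        assert table.total_proteins == sum(len(o.members) for o in ogcs)


class TestVenn:
    def test_published_cha_only_region(self):
        regions = venn_counts(OGCTable.from_counts(OGC_GROUP_COUNTS))
        assert regions["Cha"] == 7473  # Cha + ZCC + KCM single-lineage groups
        assert regions["Emb"] == OGC_GROUP_COUNTS["Emb"][1]
        assert sum(regions.values()) == 25485

    def test_all_zero(self):
        assert set(venn_counts(OGCTable()).values()) == {0}


class TestOccupancy:
    def test_counts_ogcs_not_proteins(self):
        occ = species_occupancy([_cluster(("Kni", 3), ("Zygy", 1))], TAX)
        assert occ["Kni"]["Cha"] == 1 and occ["Zygy"]["Cha"] == 1
        assert occ["Ath"] == {g: 0 for g in GROUP_LABELS}

    def test_species_sums_at_least_twice_group_counts(self, small_truth, default_taxonomy):
        ogcs = [
            _cluster(*((sp, 1) for sp in species))
            for _, (_, species) in small_truth.families.items()
        ]
        occ = species_occupancy(ogcs, default_taxonomy)
        table, _ = tabulate_groups(ogcs, default_taxonomy)
        for g in GROUP_LABELS:
            total = sum(occ[sp][g] for sp in default_taxonomy)
            assert total >= 2 * table.rows[g].ogc_count
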