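"""Phyletic-pattern classification of orthologous gene clusters (OGCs).

An OGC is a protein family spanning at least two species. Given a taxonomy
assigning each species to one of four clades — chlorophytes (Chl), the two
charophyte grades (KCM and ZCC, jointly "Cha") and embryophytes (Emb) — every
OGC falls into exactly one of nine phyletic groups according to which clades
its member species come from. Mixed groups record presence/absence across the
three major lineages (e.g. ``Cha+Emb`` = present in charophytes and land
plants, absent in the chlorophyte outgroup); single-lineage groups split the
charophytes further into Cha (both grades), ZCC-only and KCM-only.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Set, Tuple

from .errors import TaxonomyError

CLADES = ("Chl", "KCM", "ZCC", "Emb")

#: The nine phyletic group labels, in canonical (report) order.
GROUP_LABELS = (
    "Chl+Cha+Emb",
    "Cha+Emb",
    "Chl+Cha",
    "Chl+Emb",
    "Emb",
    "Cha",
    "ZCC",
    "KCM",
    "Chl",
)


class SpeciesTaxonomy:
    """Mapping of species identifiers to clades (Chl / KCM / ZCC / Emb).

    ``Cha`` is derived: the union of the KCM and ZCC clades.
    """

    def __init__(self, species_to_clade: Mapping[str, str]):
        if not species_to_clade:
            raise TaxonomyError("taxonomy must contain at least one species")
        for sp, clade in species_to_clade.items():
            if clade not in CLADES:
                raise TaxonomyError(
                    f"species {sp!r} has unknown clade {clade!r}; "
                    f"expected one of {CLADES}"
                )
        self._map: Dict[str, str] = dict(species_to_clade)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, species: str) -> bool:
        return species in self._map

    def __iter__(self):
        return iter(self._map)

    def items(self):
        return self._map.items()

    def clade_of(self, species: str) -> str:
        try:
            return self._map[species]
        except KeyError:
            raise TaxonomyError(f"species {species!r} not in taxonomy") from None

    def species_in(self, clade: str) -> Set[str]:
        if clade == "Cha":
            return {s for s, c in self._map.items() if c in ("KCM", "ZCC")}
        return {s for s, c in self._map.items() if c == clade}

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_tsv(cls, path) -> "SpeciesTaxonomy":
        mapping: Dict[str, str] = {}
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise TaxonomyError(f"{path}:{i}: expected 2 tab-separated columns")
            mapping[parts[0]] = parts[1]
        return cls(mapping)

    def to_tsv(self, path) -> None:
        lines = [f"{s}\t{c}" for s, c in sorted(self._map.items())]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class Cluster:
    """A cluster of proteins together with the species they come from."""

    members: FrozenSet[str]
    species_set: FrozenSet[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError("cluster must have at least one member")


def classify_ogc(species_set: Iterable[str], taxonomy: SpeciesTaxonomy) -> str:
    """Assign the unique phyletic group label to an OGC's species set.

    The set must contain at least two species (single-species clusters are
    removed by the retention rule before classification and are rejected
    here). Exactly one of the nine rules applies to any valid set.
    """
    species = set(species_set)
    if len(species) < 2:
        raise TaxonomyError(
            f"species set {sorted(species)} has fewer than 2 species; "
            "multi-species retention must be applied before classification"
        )
    clades = {taxonomy.clade_of(s) for s in species}
    has_chl = "Chl" in clades
    has_kcm = "KCM" in clades
    has_zcc = "ZCC" in clades
    has_cha = has_kcm or has_zcc
    has_emb = "Emb" in clades

    if has_chl and has_cha and has_emb:
        return "Chl+Cha+Emb"
    if has_cha and has_emb:
        return "Cha+Emb"
    if has_chl and has_cha:
        return "Chl+Cha"
    if has_chl and has_emb:
        return "Chl+Emb"
    if has_emb:
        return "Emb"
    if has_kcm and has_zcc:
        return "Cha"
    if has_zcc:
        return "ZCC"
    if has_kcm:
        return "KCM"
    return "Chl"


@dataclass
class GroupStats:
    ogc_count: int = 0
    protein_count: int = 0
    max_species: int = 0


@dataclass
class OGCTable:
    """Per-group OGC/protein counts plus the observed maximum species span."""

    rows: Dict[str, GroupStats] = field(
        default_factory=lambda: {g: GroupStats() for g in GROUP_LABELS}
    )

    @property
    def total_ogcs(self) -> int:
        return sum(r.ogc_count for r in self.rows.values())

    @property
    def total_proteins(self) -> int:
        return sum(r.protein_count for r in self.rows.values())

    @classmethod
    def from_counts(cls, counts: Mapping[str, Tuple[int, int]]) -> "OGCTable":
        """Build a table from per-group ``(protein_count, ogc_count)`` pairs."""
        table = cls()
        for group, (n_prot, n_ogc) in counts.items():
            if group not in table.rows:
                raise TaxonomyError(f"unknown group label {group!r}")
            table.rows[group].protein_count = int(n_prot)
            table.rows[group].ogc_count = int(n_ogc)
        return table

    def to_tsv(self, path) -> None:
        lines = ["group\tmax_species\tprotein_count\togc_count"]
        for g in GROUP_LABELS:
            r = self.rows[g]
            lines.append(f"{g}\t{r.max_species}\t{r.protein_count}\t{r.ogc_count}")
        lines.append(f"Total\t\t{self.total_proteins}\t{self.total_ogcs}")
        Path(path).write_text("\n".join(lines) + "\n")


def tabulate_groups(
    ogcs: Iterable[Cluster], taxonomy: SpeciesTaxonomy
) -> Tuple[OGCTable, Dict[str, str]]:
    """Classify every OGC and aggregate counts per phyletic group.

    Returns the table and a mapping of each cluster (keyed by its
    lexicographically smallest member) to its group label.
    """
    table = OGCTable()
    labels: Dict[str, str] = {}
    for ogc in ogcs:
        group = classify_ogc(ogc.species_set, taxonomy)
        labels[min(ogc.members)] = group
        row = table.rows[group]
        row.ogc_count += 1
        row.protein_count += len(ogc.members)
        row.max_species = max(row.max_species, len(ogc.species_set))
    return table, labels


#: Venn regions over the three major lineages. The charophyte-only region
#: pools the Cha, ZCC and KCM single-lineage groups.
VENN_REGIONS = ("Chl+Cha+Emb", "Cha+Emb", "Chl+Cha", "Chl+Emb", "Emb", "Cha", "Chl")


def venn_counts(table: OGCTable) -> Dict[str, int]:
    """Collapse the nine-group table to the 7 regions of a 3-set Venn diagram."""
    regions = {r: table.rows[r].ogc_count for r in VENN_REGIONS}
    regions["Cha"] = (
        table.rows["Cha"].ogc_count
        + table.rows["ZCC"].ogc_count
        + table.rows["KCM"].ogc_count
    )
    return regions


def species_occupancy(
    ogcs: Iterable[Cluster], taxonomy: SpeciesTaxonomy
) -> Dict[str, Dict[str, int]]:
    """Count, per species and per group, the OGCs containing >=1 of its proteins.

    Counts are OGCs, not proteins: an OGC with five proteins of one species
    contributes 1 to that species' tally.
    """
    occ: Dict[str, Dict[str, int]] = {
        s: {g: 0 for g in GROUP_LABELS} for s in taxonomy
    }
    for ogc in ogcs:
        group = classify_ogc(ogc.species_set, taxonomy)
        for sp in ogc.species_set:
            occ[sp][group] += 1
    return occ


def write_occupancy_tsv(occ: Mapping[str, Mapping[str, int]], path) -> None:
    lines = ["species\t" + "\t".join(GROUP_LABELS)]
    for sp in sorted(occ):
        lines.append(sp + "\t" + "\t".join(str(occ[sp][g]) for g in GROUP_LABELS))
    Path(path).write_text("\n".join(lines) + "\n")
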