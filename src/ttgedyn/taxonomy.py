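"""Taxonomic roll-up of species-level OTUs.

Three nested levels are used throughout: SLOTU (species-level phylotype),
GLOTU (genus or family), and PLOTU (phylum, with the phylum Firmicutes
split into its classes Bacilli / Clostridia / Negativicutes). The default
map groups *Escherichia*, *Enterobacter* and *Klebsiella* into
Enterobacteriaceae (16S relatedness within the family) and sends
*Clostridium innocuum* to Erysipelotrichaceae rather than the genus
*Clostridium*, whose name it carries only for historical reasons.
"""

from __future__ import annotations

from collections import Counter
from importlib import resources

from .assign import AFFILIATED, Assignment
from .errors import UnmappedTaxonError
from .model import TaxonomyMap

SLOTU, GLOTU, PLOTU = "slotu", "glotu", "plotu"

#: SLOTU -> GLOTU entries that intentionally contradict genus-name
#: derivation and must survive into any user-edited default map.
DEFAULT_OVERRIDES = {
    "Escherichia coli": "Enterobacteriaceae",
    "Klebsiella oxytoca": "Enterobacteriaceae",
    "Klebsiella pneumoniae": "Enterobacteriaceae",
    "Enterobacter cloacae": "Enterobacteriaceae",
    "Clostridium innocuum": "Erysipelotrichaceae",
    "Sarcina ventriculi": "Sarcina/Clostridiaceae",
    "Burkholderiales ND": "Burkholderiales",
}


def default_taxonomy() -> TaxonomyMap:
    """The packaged taxonomy map covering the 50 reference SLOTUs."""
    from .io import read_taxonomy  # local import to avoid cycle at import

    path = resources.files("ttgedyn.data") / "taxonomy_default.tsv"
    with resources.as_file(path) as p:
        return read_taxonomy(p, overrides=DEFAULT_OVERRIDES)


def rollup_glotu(slotu_id: str, tmap: TaxonomyMap) -> str:
    """GLOTU of a SLOTU: override, then explicit map, then genus name."""
    if slotu_id in tmap.overrides:
        return tmap.overrides[slotu_id]
    if slotu_id in tmap.slotu_to_glotu:
        return tmap.slotu_to_glotu[slotu_id]
    genus = slotu_id.split()[0] if slotu_id.split() else ""
    if genus in tmap.glotu_to_plotu:
        return genus
    raise UnmappedTaxonError(f"SLOTU {slotu_id!r} has no GLOTU mapping")


def rollup_plotu(glotu_id: str, tmap: TaxonomyMap) -> str:
    if glotu_id in tmap.glotu_to_plotu:
        return tmap.glotu_to_plotu[glotu_id]
    raise UnmappedTaxonError(f"GLOTU {glotu_id!r} has no PLOTU mapping")


def slotu_to_plotu(slotu_id: str, tmap: TaxonomyMap) -> str:
    return rollup_plotu(rollup_glotu(slotu_id, tmap), tmap)


def distinct_groups(assignments: list[Assignment], tmap: TaxonomyMap,
                    level: str) -> Counter:
    """Distinct groups represented by >= 1 affiliated band, with counts."""
    if level not in (SLOTU, GLOTU, PLOTU):
        raise ValueError(f"level must be one of slotu/glotu/plotu, "
                         f"got {level!r}")
    counts: Counter = Counter()
    for a in assignments:
        if a.status != AFFILIATED:
            continue
        group = a.slotu_id
        if level in (GLOTU, PLOTU):
            group = rollup_glotu(group, tmap)
        if level == PLOTU:
            group = rollup_plotu(group, tmap)
        counts[group] += 1
    return counts
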