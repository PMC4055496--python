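"""Gadoid taxonomy used throughout the package.

The survey concerns white-fish products sold as cod, haddock, pollock,
hake or whiting.  Two congener pairs are indistinguishable at COI
(identical barcodes) and are therefore treated as single assignable
*groups*: Pacific/Greenland cod (*Gadus macrocephalus* / *G. ogac*) and
Alaskan/Norwegian pollock (*G. chalcogrammus* / *G. finnmarchica*).
All other species stand alone in their own group.
"""

from __future__ import annotations

# group id -> binomials that share an identical COI barcode
GROUPS: dict[str, frozenset[str]] = {
    "morhua": frozenset({"Gadus morhua"}),
    "macrocephalus-group": frozenset({"Gadus macrocephalus", "Gadus ogac"}),
    "chalcogramma-group": frozenset({"Gadus chalcogrammus", "Gadus finnmarchica"}),
    "aeglefinus": frozenset({"Melanogrammus aeglefinus"}),
    "merlangus": frozenset({"Merlangius merlangus"}),
    "poutassou": frozenset({"Micromesistius poutassou"}),
    "capensis": frozenset({"Merluccius capensis"}),
    "paradoxus": frozenset({"Merluccius paradoxus"}),
    "pangasius": frozenset({"Pangasius hypophthalmus"}),
}

SPECIES_TO_GROUP: dict[str, str] = {
    sp: gid for gid, members in GROUPS.items() for sp in members
}

# spelling variants seen on labels / in older literature
ALIASES: dict[str, str] = {
    "Gadus chalcogramma": "Gadus chalcogrammus",
    "Theragra chalcogramma": "Gadus chalcogrammus",
    "Pangasius hypophthalamus": "Pangasius hypophthalmus",
}


def canonical_species(name: str) -> str:
    """Normalise a binomial to its canonical spelling."""
    name = " ".join(name.split())
    return ALIASES.get(name, name)


def group_of(species: str) -> str:
    """Return the assignable group id for a binomial.

    Raises
    ------
    KeyError
        If the species is not part of the reference taxonomy.
    """
    return SPECIES_TO_GROUP[canonical_species(species)]


# Guide phylogeny for the synthetic reference panel, as
# (node name, branch length to parent, children).  Leaves are group ids;
# branch lengths are in p-distance units so that leaf-to-leaf path
# lengths give the target pairwise divergences.  Geometry is chosen so
# that every group's nearest neighbour in the panel is its designated
# sister taxon and every cross-group divergence exceeds 2%.
GUIDE_TREE = (
    "root",
    0.0,
    (
        (
            "gadid",
            0.02,
            (
                (
                    "gadus",
                    0.02,
                    (
                        (
                            "morhua-chalcogramma",
                            0.015,
                            (
                                ("morhua", 0.02, ()),
                                ("chalcogramma-group", 0.025, ()),
                            ),
                        ),
                        ("macrocephalus-group", 0.045, ()),
                    ),
                ),
                (
                    "aeglefinus-merlangus",
                    0.015,
                    (
                        ("aeglefinus", 0.035, ()),
                        ("merlangus", 0.03, ()),
                    ),
                ),
            ),
        ),
        ("poutassou", 0.055, ()),
        (
            "merluccius",
            0.05,
            (
                ("capensis", 0.02, ()),
                ("paradoxus", 0.025, ()),
            ),
        ),
        ("pangasius", 0.12, ()),
    ),
)


def group_divergences() -> dict[tuple[str, str], float]:
    """Pairwise p-distance targets between groups, from the guide tree."""
    pairs: dict[tuple[str, str], float] = {}

    def collect(node) -> dict[str, float]:
        name, length, children = node
        if not children:
            return {name: length}
        per_child = [collect(child) for child in children]
        for i in range(len(per_child)):
            for j in range(i + 1, len(per_child)):
                for la, da in per_child[i].items():
                    for lb, db in per_child[j].items():
                        pairs[tuple(sorted((la, lb)))] = da + db
        merged = {leaf: d + length for sub in per_child for leaf, d in sub.items()}
        return merged

    collect(GUIDE_TREE)
    return pairs


def default_divergence_spec() -> dict[tuple[str, str], float]:
    """Species-pair -> target p-distance for the default reference panel.

    Congeners within a group get 0; cross-group pairs get the guide-tree
    path length between their groups.
    """
    by_group = group_divergences()
    species = sorted(SPECIES_TO_GROUP)
    spec: dict[tuple[str, str], float] = {}
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            ga, gb = SPECIES_TO_GROUP[a], SPECIES_TO_GROUP[b]
            if ga == gb:
                spec[(a, b)] = 0.0
            else:
                spec[(a, b)] = by_group[tuple(sorted((ga, gb)))]
    return spec


DEFAULT_SPECIES_SPEC: list[tuple[str, str]] = [
    (sp, SPECIES_TO_GROUP[sp]) for sp in sorted(SPECIES_TO_GROUP)
]

# Probe target species of the two TaqMan assays (dye layer -> binomial).
DYE_TARGETS: dict[str, str] = {
    "COD": "Gadus morhua",
    "HAD": "Melanogrammus aeglefinus",
}
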