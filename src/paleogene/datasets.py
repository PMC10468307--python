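"""Built-in small datasets for examples and tests.

The primate timetree here is a *synthetic reconstruction*: a 31-species
ultrametric tree assembled programmatically from published primate divergence
times (root at 74 MYA, Colobinae crown with the African/Asian split, the
Trachypithecus–Rhinopithecus split at 7.67 MYA, the two ~10.2–10.5 MYA
cercopithecine divergences, etc.), not a database export.  It reproduces the
topology and node ages a user would obtain from a synthesized timetree of
these species closely enough to exercise every tree-facing code path;
*Cebus imitator* is deliberately left out so that grafting it at 1.7 MYA (its
published split from *C. capucinus*) demonstrates leaf grafting.
"""

from __future__ import annotations

from .timetree import TimeTree, read_timetree

__all__ = [
    "synthetic_primate_newick",
    "synthetic_primate_timetree",
    "synthetic_primate_age_ranges",
    "COLOBINAE",
]

#: the five colobine species present in the tree (subfamily Colobinae here
#: means "the colobines among the sampled species", not the full subfamily)
COLOBINAE = frozenset(
    {
        "Piliocolobus_tephrosceles",
        "Colobus_angolensis",
        "Trachypithecus_francoisi",
        "Rhinopithecus_roxellana",
        "Rhinopithecus_bieti",
    }
)

# (name-or-None, age MYA, children) — ages are point estimates drawn from the
# primate literature; leaves are (name, 0, ())
_TREE = (
    "Primates", 74.0, (
        ("Strepsirrhini", 59.3, (
            ("Otolemur_garnettii", 0, ()),
            (None, 38.6, (
                ("Microcebus_murinus", 0, ()),
                (None, 31.2, (
                    ("Propithecus_coquereli", 0, ()),
                    (None, 21.5, (
                        ("Lemur_catta", 0, ()),
                        ("Prolemur_simus", 0, ()),
                    )),
                )),
            )),
        )),
        ("Haplorhini", 69.0, (
            ("Carlito_syrichta", 0, ()),
            ("Simiiformes", 43.2, (
                ("Platyrrhini", 19.7, (
                    ("Callithrix_jacchus", 0, ()),
                    (None, 16.9, (
                        ("Aotus_nancymaae", 0, ()),
                        ("Cebinae", 14.1, (
                            ("Saimiri_boliviensis", 0, ()),
                            (None, 6.2, (
                                ("Cebus_capucinus", 0, ()),
                                ("Sapajus_apella", 0, ()),
                            )),
                        )),
                    )),
                )),
                ("Catarrhini", 29.4, (
                    ("Cercopithecoidea", 17.6, (
                        ("Cercopithecinae", 13.7, (
                            ("Chlorocebus_sabaeus", 0, ()),
                            (None, 10.45, (
                                (None, 5.3, (
                                    ("Macaca_nemestrina", 0, ()),
                                    (None, 3.9, (
                                        ("Macaca_mulatta", 0, ()),
                                        ("Macaca_fascicularis", 0, ()),
                                    )),
                                )),
                                (None, 8.0, (
                                    (None, 4.5, (
                                        ("Mandrillus_leucophaeus", 0, ()),
                                        ("Cercocebus_atys", 0, ()),
                                    )),
                                    (None, 4.1, (
                                        ("Papio_anubis", 0, ()),
                                        ("Theropithecus_gelada", 0, ()),
                                    )),
                                )),
                            )),
                        )),
                        ("Colobinae", 12.3, (
                            (None, 10.21, (
                                ("Piliocolobus_tephrosceles", 0, ()),
                                ("Colobus_angolensis", 0, ()),
                            )),
                            (None, 7.67, (
                                ("Trachypithecus_francoisi", 0, ()),
                                (None, 1.6, (
                                    ("Rhinopithecus_roxellana", 0, ()),
                                    ("Rhinopithecus_bieti", 0, ()),
                                )),
                            )),
                        )),
                    )),
                    ("Hominoidea", 20.2, (
                        (None, 8.3, (
                            ("Hylobates_moloch", 0, ()),
                            ("Nomascus_leucogenys", 0, ()),
                        )),
                        ("Hominidae", 15.8, (
                            ("Pongo_abelii", 0, ()),
                            ("Homininae", 9.1, (
                                ("Gorilla_gorilla", 0, ()),
                                (None, 6.4, (
                                    ("Homo_sapiens", 0, ()),
                                    ("Pan", 2.4, (
                                        ("Pan_paniscus", 0, ()),
                                        ("Pan_troglodytes", 0, ()),
                                    )),
                                )),
                            )),
                        )),
                    )),
                )),
            )),
        )),
    ),
)

#: 95%-style confidence ranges for a few key nodes (synthetic, bracketing the
#: point estimates the way a synthesized timetree reports them)
_AGE_RANGES = {
    "Primates": (71.0, 77.0),
    "Homininae": (8.3, 9.9),
    "Pan": (1.8, 3.1),
    "Colobinae": (11.0, 13.8),
    "Trachypithecus_francoisi,Rhinopithecus_roxellana": (6.9, 8.5),
    "Cebus_capucinus,Sapajus_apella": (5.2, 7.3),
}


def _to_newick(node, parent_age: float | None) -> str:
    name, age, children = node
    if not children:
        body = name
    else:
        inner = ",".join(_to_newick(c, age) for c in children)
        body = f"({inner}){name or ''}"
    if parent_age is None:
        return body
    return f"{body}:{parent_age - age:g}"


def synthetic_primate_newick() -> str:
    """Newick text of the synthetic 31-species primate timetree."""
    return _to_newick(_TREE, None) + ";"


def synthetic_primate_age_ranges() -> dict[str, tuple[float, float]]:
    """Sidecar-style age ranges keyed by node label or taxon pair."""
    return dict(_AGE_RANGES)


def synthetic_primate_timetree(with_ranges: bool = True) -> TimeTree:
    """The synthetic 31-species primate timetree as a :class:`TimeTree`."""
    return read_timetree(
        synthetic_primate_newick(),
        age_ranges=_AGE_RANGES if with_ranges else None,
    )
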