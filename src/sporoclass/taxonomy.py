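"""Label vocabulary for the fungal-spore reference panel.

The study panel comprises 17 certified fungal strains. Each event carries a
species label drawn from this closed vocabulary; two coarser groupings are
derived from it:

* **genus** — the first whitespace-delimited token of the species label
  (10 distinct genera over the 17 species), used when classification results
  are aggregated to the taxonomic level routine aerobiology works at;
* **Rapid-E+ class** — the 7-class pooling used for the fluorescence
  instrument, where the five *Alternaria* species are measured as a single
  mixed "Alternaria spp." sample and the three *Cladosporium* species as
  "Cladosporium spp.".
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "SPECIES_LABELS",
    "GENUS_LABELS",
    "RAPID_E_CLASSES",
    "TaxonLabel",
    "VocabularyError",
    "GroupingError",
    "species_to_genus",
    "rapid_e_grouping",
    "taxon",
]

#: The 17 study labels, in the panel's alphabetical order.
SPECIES_LABELS: tuple[str, ...] = (
    "Alternaria alternata",
    "Alternaria arborescens",
    "Alternaria botrytis",
    "Alternaria chartarum",
    "Alternaria terricola",
    "Botrytis cinerea",
    "Chaetomium globosum",
    "Cladosporium cladosporioides",
    "Cladosporium herbarum",
    "Cladosporium sphaerospermum",
    "Curvularia caricae-papayae",
    "Epicoccum nigrum",
    "Exserohilum rostratum",
    "Fusarium culmorum",
    "Fusarium pseudocircinatum",
    "Pithomyces chartarum",
    "Stemphylium vesicarium",
)

#: Species pooled for the Rapid-E+ instrument (mixed-sample aerosolization).
_POOLED = {
    "Alternaria": "Alternaria spp.",
    "Cladosporium": "Cladosporium spp.",
}

#: Species measured individually on the Rapid-E+.
_RAPID_E_SINGLE = (
    "Botrytis cinerea",
    "Curvularia caricae-papayae",
    "Epicoccum nigrum",
    "Exserohilum rostratum",
    "Pithomyces chartarum",
)


class VocabularyError(KeyError):
    """A species label outside the 17-label study vocabulary."""


class GroupingError(KeyError):
    """A species label with no Rapid-E+ pooled class (not measured there)."""


def species_to_genus(species_label: str) -> str:
    """Return the genus token of a study species label.

    The genus is the first whitespace-delimited token of the label; the 17
    labels map onto exactly 10 genera.

    Raises
    ------
    VocabularyError
        If ``species_label`` is not one of the 17 study labels.
    """
    if species_label not in SPECIES_LABELS:
        raise VocabularyError(
            f"unknown species label {species_label!r}; expected one of the "
            f"{len(SPECIES_LABELS)} study labels"
        )
    return species_label.split()[0]


GENUS_LABELS: tuple[str, ...] = tuple(
    dict.fromkeys(s.split()[0] for s in SPECIES_LABELS)
)

RAPID_E_CLASSES: tuple[str, ...] = (
    "Alternaria spp.",
    "Botrytis cinerea",
    "Cladosporium spp.",
    "Curvularia caricae-papayae",
    "Epicoccum nigrum",
    "Exserohilum rostratum",
    "Pithomyces chartarum",
)


def rapid_e_grouping(species_label: str) -> str:
    """Return the pooled Rapid-E+ class name for a species label.

    Alternaria and Cladosporium species pool into "<Genus> spp."; the five
    species measured individually keep their own name; the remaining study
    species were not measured on the Rapid-E+ and raise ``GroupingError``.
    """
    genus = species_to_genus(species_label)
    if genus in _POOLED:
        return _POOLED[genus]
    if species_label in _RAPID_E_SINGLE:
        return species_label
    raise GroupingError(
        f"species {species_label!r} was not measured on the Rapid-E+ "
        f"(no pooled class)"
    )


@dataclass(frozen=True)
class TaxonLabel:
    """A study label together with its derived genus and Rapid-E+ class.

    ``rapid_e_class`` is ``None`` for species not measured on that
    instrument.
    """

    species_label: str
    genus: str
    rapid_e_class: str | None

    def __post_init__(self) -> None:
        if self.species_label not in SPECIES_LABELS:
            raise VocabularyError(
                f"unknown species label {self.species_label!r}"
            )


def taxon(species_label: str) -> TaxonLabel:
    """Build the full :class:`TaxonLabel` for a study species label."""
    genus = species_to_genus(species_label)
    try:
        pooled: str | None = rapid_e_grouping(species_label)
    except GroupingError:
        pooled = None
    return TaxonLabel(species_label, genus, pooled)
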