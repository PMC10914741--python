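"""Synthetic occurrence datasets with known gathering structure.

The generator emulates what duplicated herbarium records look like after GBIF
aggregation: each collection event is duplicated across institutions, and each
duplicate independently accumulates the error modes seen in real aggregated
data — conflicting identifications, synonym substitutions, lost collection
numbers or collector strings, swapped or zeroed coordinates, centroid
substitution and dropped descriptive fields. Injected GBIF issue tokens are
kept consistent with the injected coordinate errors. Ground truth (the true
event key and taxon of every record) is returned alongside, so pipeline
recovery is directly measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from gatherparse.collectors import fold_ascii_upper
from gatherparse.ingest import get_profile, select_fields

#: accepted binomials used as the default species pool (Myrtaceae-flavoured)
DEFAULT_SPECIES = (
    "Eugenia uniflora", "Eugenia punicifolia", "Eugenia involucrata",
    "Myrcia splendens", "Myrcia guianensis", "Myrcia tomentosa",
    "Psidium guajava", "Psidium cattleyanum", "Campomanesia hirsuta",
    "Campomanesia xanthocarpa", "Plinia cauliflora", "Myrciaria dubia",
    "Calyptranthes concinna", "Syzygium cumini", "Melaleuca quinquenervia",
    "Corymbia citriodora", "Eucalyptus globulus", "Myrtus communis",
    "Pimenta dioica", "Blepharocalyx salicifolius",
)

_SURNAMES = (
    "Gardner", "Müller", "Silva", "Hopkins", "Oliveira", "Souza", "Ferreira",
    "Lima", "Araújo", "Barbosa", "Nicolson", "Costa", "Gonçalves", "Ribeiro",
    "Martinelli", "Hatschbach", "Irwin", "Prance", "Ducke", "Glaziou",
)
_INSTITUTIONS = ("K", "NY", "E", "US", "MO", "RB", "INPA", "S", "F", "P")
_MUNICIPALITIES = ("Piumhi", "Manaus", "Ouro Preto", "Ilhéus", "Petrópolis", "Cuiabá")
_STATES = ("Minas Gerais", "Amazonas", "Bahia", "Rio de Janeiro", "Mato Grosso")
_HABITATS = ("Cerrado sensu stricto", "Gallery forest", "Restinga", "Terra firme forest",
             "Campo rupestre")
_FIELD_NOTES = ("Shrub 2 m, flowers white", "Tree 8 m, fruits green",
                "Treelet in flower", "Common along trail")
_LOCALITIES = ("Trail to Serra do Cipó", "Margin of Rio Negro", "Road BR-262 km 45",
               "Fazenda Boa Vista", "Parque Estadual do Itacolomi")

#: 33-column layout mirroring a WCVP names export
WCVP_COLUMNS_33 = (
    "plant_name_id", "ipni_id", "taxon_rank", "taxon_status", "family",
    "genus_hybrid", "genus", "species_hybrid", "species", "infraspecific_rank",
    "infraspecies", "parenthetical_author", "primary_author", "publication_author",
    "place_of_publication", "volume_and_page", "first_published",
    "nomenclatural_remarks", "geographic_area", "lifeform_description",
    "climate_description", "taxon_name", "taxon_authors", "accepted_plant_name_id",
    "basionym_plant_name_id", "replaced_synonym_author", "homotypic_synonym",
    "parent_plant_name_id", "powo_id", "hybrid_formula", "reviewed",
    "basionym_author", "nomenclatural_status",
)

_SYNONYM_GENUS_PREFIXES = ("Pseudo", "Neo", "Para", "Archi")


def synonym_name(species: str, j: int = 0) -> str:
    """Deterministic synonym string for an accepted binomial (j-th synonym)."""
    genus, epithet = species.split(" ", 1)
    return f"{_SYNONYM_GENUS_PREFIXES[j % len(_SYNONYM_GENUS_PREFIXES)]}{genus.lower()} {epithet}"


def generate_mini_wcvp(species=DEFAULT_SPECIES, synonyms_per_species: int = 1,
                       family: str = "Myrtaceae") -> pd.DataFrame:
    """A small WCVP-style names table: accepted rows plus resolving synonyms."""
    if not species:
        raise ValueError("species list must be non-empty")
    rows = []
    next_id = 1

    def _row(name, status, rank, accepted_id, own_id):
        genus, rest = name.split(" ", 1)
        r = {c: "" for c in WCVP_COLUMNS_33}
        r.update(
            plant_name_id=own_id, taxon_rank=rank, taxon_status=status,
            family=family, genus=genus, species=rest.split(" ")[0],
            taxon_name=name, taxon_authors="Auct.",
            accepted_plant_name_id=accepted_id, reviewed="Y",
        )
        return r

    for sp in species:
        acc_id = f"wcvp-{next_id:06d}"
        next_id += 1
        rows.append(_row(sp, "Accepted", "Species", acc_id, acc_id))
        for j in range(synonyms_per_species):
            syn_id = f"wcvp-{next_id:06d}"
            next_id += 1
            rows.append(_row(synonym_name(sp, j), "Synonym", "Species", acc_id, syn_id))
    return pd.DataFrame(rows, columns=list(WCVP_COLUMNS_33))


@dataclass(frozen=True)
class ErrorRates:
    """Per-duplicate corruption probabilities (all in [0, 1]).

    Defaults describe a plausibly messy aggregated download; set everything to
    0 for the noiseless recovery scenario.
    """

    conflicting_identification: float = 0.10
    synonym_substitution: float = 0.15
    missing_record_number: float = 0.05
    missing_collector: float = 0.02
    swapped_coordinates: float = 0.01
    zero_coordinate: float = 0.01
    centroid_substitution: float = 0.02
    drop_field: float = 0.15

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")

    @classmethod
    def none(cls) -> "ErrorRates":
        return cls(0, 0, 0, 0, 0, 0, 0, 0)


@dataclass(frozen=True)
class SyntheticScenario:
    """Study conditions for one synthetic dataset.

    ``duplicates_per_event`` is either a fixed integer k (every event has k
    records) or a string ``"poisson:m"`` drawing each event's record count
    from a Poisson with mean m, truncated below at 1.
    """

    n_events: int = 100
    duplicates_per_event: int | str = "poisson:1.4"
    error_rates: ErrorRates = field(default_factory=ErrorRates)
    species: tuple[str, ...] = DEFAULT_SPECIES
    synonyms_per_species: int = 1
    family: str = "Myrtaceae"
    seed: int = 0


def _draw_group_sizes(scenario: SyntheticScenario, rng: np.random.Generator) -> np.ndarray:
    spec = scenario.duplicates_per_event
    if isinstance(spec, int):
        return np.full(scenario.n_events, spec)
    if isinstance(spec, str) and spec.startswith("poisson:"):
        lam = float(spec.split(":", 1)[1])
        return np.maximum(1, rng.poisson(lam, scenario.n_events))
    if isinstance(spec, str) and spec.startswith("fixed:"):
        return np.full(scenario.n_events, int(spec.split(":", 1)[1]))
    raise ValueError(f"unsupported duplicates_per_event spec: {spec!r}")


def _render_collector(surname: str, initial: str, rng: np.random.Generator) -> str:
    other = f"{_SURNAMES[rng.integers(len(_SURNAMES))]}, {chr(65 + rng.integers(26))}."
    dialects = (
        f"{surname}, {initial}.",
        f"{initial}. {surname}",
        f"{surname}, {initial}.; {other}",
        f"{surname} et al.",
        f"{fold_ascii_upper(surname).title()}, {initial}.",  # diacritics stripped in transit
    )
    return dialects[rng.integers(len(dialects))]


def _render_number(number: int, rng: np.random.Generator) -> str:
    return str(number) if rng.random() < 0.8 else f"no. {number}"


def generate_occurrences(scenario: SyntheticScenario) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a GBIF-dialect occurrence table plus its ground truth.

    Returns ``(occurrences, truth)`` where truth maps each ``gbifID`` to its
    true event key and true accepted taxon. Deterministic given the scenario
    seed; all randomness flows through one seeded generator.
    """
    rng = np.random.default_rng(scenario.seed)
    rates = scenario.error_rates
    sizes = _draw_group_sizes(scenario, rng)
    species = list(scenario.species)
    collector_counter: dict[int, int] = {}
    occ_rows, truth_rows = [], []
    rid = 0
    for ev in range(scenario.n_events):
        sp = species[rng.integers(len(species))]
        ci = int(rng.integers(len(_SURNAMES)))
        surname = _SURNAMES[ci]
        initial = chr(65 + rng.integers(26))
        collector_counter[ci] = collector_counter.get(ci, 100) + 1 + int(rng.integers(5))
        number = collector_counter[ci]
        lat = round(float(rng.uniform(-30, 5)), 4)
        lon = round(float(rng.uniform(-75, -35)), 4)
        year = str(int(rng.integers(1930, 2021)))
        locality = _LOCALITIES[rng.integers(len(_LOCALITIES))]
        municipality = _MUNICIPALITIES[rng.integers(len(_MUNICIPALITIES))]
        state = _STATES[rng.integers(len(_STATES))]
        habitat = _HABITATS[rng.integers(len(_HABITATS))]
        notes = _FIELD_NOTES[rng.integers(len(_FIELD_NOTES))]
        true_key = f"{scenario.family.upper()}_{fold_ascii_upper(surname)}_{number}"
        for _ in range(int(sizes[ev])):
            rid += 1
            gbif_id = str(3000000000 + rid)
            inst = _INSTITUTIONS[rng.integers(len(_INSTITUTIONS))]
            issues: list[str] = []
            name = sp
            if rng.random() < rates.synonym_substitution:
                name = synonym_name(sp, int(rng.integers(max(1, scenario.synonyms_per_species))))
            if rng.random() < rates.conflicting_identification:
                name = species[rng.integers(len(species))]
            rec_by = _render_collector(surname, initial, rng)
            if rng.random() < rates.missing_collector:
                rec_by = ""
            rec_no = _render_number(number, rng)
            if rng.random() < rates.missing_record_number:
                rec_no = "s.n." if rng.random() < 0.5 else ""
            rlat, rlon = lat, lon
            if rng.random() < rates.swapped_coordinates:
                rlat, rlon = lon, lat
                issues.append("PRESUMED_SWAPPED_COORDINATE")
            if rng.random() < rates.zero_coordinate:
                rlat, rlon = 0.0, 0.0
                issues.append("ZERO_COORDINATE")
            elif rng.random() < rates.centroid_substitution:
                rlat, rlon = float(int(rlat)), float(int(rlon))
                issues.append("COORDINATE_ROUNDED")

            def maybe(v: str) -> str:
                return "" if rng.random() < rates.drop_field else v

            occ_rows.append({
                "gbifID": gbif_id,
                "family": scenario.family,
                "scientificName": name,
                "recordedBy": rec_by,
                "recordNumber": rec_no,
                "year": maybe(year),
                "institutionCode": inst,
                "catalogNumber": f"{inst}-{int(rng.integers(10000, 99999))}",
                "locality": maybe(locality),
                "municipality": maybe(municipality),
                "stateProvince": maybe(state),
                "countryCode": "BR",
                "habitat": maybe(habitat),
                "fieldNotes": maybe(notes),
                "decimalLatitude": f"{rlat}",
                "decimalLongitude": f"{rlon}",
                "basisOfRecord": "PRESERVED_SPECIMEN",
                "occurrenceStatus": "PRESENT",
                "issue": ";".join(issues),
            })
            truth_rows.append({
                "gbifID": gbif_id,
                "true_event": true_key,
                "true_taxon": sp,
            })
    occ = pd.DataFrame(occ_rows, dtype=str)
    occ = select_fields(occ, get_profile("standard"))
    truth = pd.DataFrame(truth_rows, dtype=str)
    return occ, truth
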