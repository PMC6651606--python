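"""Rule-based assignment of proteins to the 11 UPS gene families.

Families are defined by required combinations of protein domains (a protein
matches a family when all domains of at least one combination are present
among its E-value-filtered hits).  Domain presence alone decides membership;
hit coordinates are carried but not used.  A protein matching several
families is resolved by a fixed priority order.  The accessory domains left
over after removing the family-defining ones form the subfamily signature
used downstream for tandem-duplication testing and domain enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

UPS_FAMILIES = ("E1", "E2", "FBX", "RING", "BTB", "HECT", "APC", "Cullin", "Skp1", "RP", "CP")
DEFAULT_PRIORITY = ("Cullin", "APC", "RP", "CP", "E1", "HECT", "E2", "Skp1", "FBX", "RING", "BTB")
DOMAIN_EVALUE_CUTOFF = 1.0

HIT_COLUMNS = ["locus", "domain", "evalue", "start", "end"]


@dataclass(frozen=True)
class DomainHit:
    locus_id: str
    domain_name: str
    e_value: float
    start: int
    end: int

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError(f"{self.locus_id}/{self.domain_name}: negative E-value")
        if self.start > self.end:
            raise ValueError(f"{self.locus_id}/{self.domain_name}: start > end")


@dataclass(frozen=True)
class FamilyRule:
    family_name: str
    required_combinations: tuple[frozenset[str], ...]
    excluded_domains: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.required_combinations or any(not c for c in self.required_combinations):
            raise ValueError(f"{self.family_name}: combinations must be non-empty")

    @property
    def defining_domains(self) -> frozenset[str]:
        out: set[str] = set()
        for comb in self.required_combinations:
            out |= comb
        return frozenset(out)

    def matches(self, domains: set[str]) -> bool:
        usable = domains - self.excluded_domains
        return any(comb <= usable for comb in self.required_combinations)


@dataclass(frozen=True)
class FamilyAssignment:
    locus_id: str
    family_name: str
    subfamily_signature: tuple[str, ...]
    is_pseudogene: bool = False


def default_rules() -> tuple[list[FamilyRule], tuple[str, ...]]:
    """The shipped family rule set and its priority order."""
    text = resources.files("upsdiverge.data").joinpath("family_rules.yaml").read_text()
    return load_rules_from_yaml(text)


def load_rules_from_yaml(text: str) -> tuple[list[FamilyRule], tuple[str, ...]]:
    raw = yaml.safe_load(text)
    priority = tuple(raw.get("priority", DEFAULT_PRIORITY))
    rules = [
        FamilyRule(
            family_name=name,
            required_combinations=tuple(frozenset(c) for c in spec["combinations"]),
            excluded_domains=frozenset(spec.get("excluded", [])),
        )
        for name, spec in raw["families"].items()
    ]
    return rules, priority


def load_domain_hits(path, e_value_cutoff: float = DOMAIN_EVALUE_CUTOFF) -> list[DomainHit]:
    """Read a TSV domain-hit table (locus, domain, evalue, start, end),
    dropping hits above the E-value cutoff."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    hits: list[DomainHit] = []
    dropped = 0
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            hit = DomainHit(
                locus_id=str(row.locus),
                domain_name=str(row.domain),
                e_value=float(row.evalue),
                start=int(row.start),
                end=int(row.end),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
        if hit.e_value > e_value_cutoff:
            dropped += 1
            continue
        hits.append(hit)
    if dropped:
        logger.info("dropped %d domain hits above E-value cutoff %g", dropped, e_value_cutoff)
    return hits


def assign_families(
    hits: Iterable[DomainHit],
    rules: Sequence[FamilyRule] | None = None,
    priority: Sequence[str] | None = None,
    pseudogene_flags: Mapping[str, bool] | None = None,
) -> list[FamilyAssignment]:
    """Assign each locus to exactly one family by its domain content.

    Conflicts between families are resolved by ``priority`` (default: rarer
    and multi-domain-defined families first).  Loci matching no family are
    excluded with a logged reason.  Exact duplicate hit rows raise.
    """
    if rules is None:
        rules, default_priority = default_rules()
        priority = priority or default_priority
    priority = tuple(priority or DEFAULT_PRIORITY)
    by_name = {rule.family_name: rule for rule in rules}
    unknown = [name for name in priority if name not in by_name]
    if unknown:
        raise ValueError(f"priority names missing from rules: {unknown}")

    domains: dict[str, set[str]] = {}
    seen: set[tuple] = set()
    for hit in hits:
        key = (hit.locus_id, hit.domain_name, hit.start, hit.end)
        if key in seen:
            raise ValueError(f"duplicate domain hit for locus {hit.locus_id}: {hit.domain_name}")
        seen.add(key)
        domains.setdefault(hit.locus_id, set()).add(hit.domain_name)

    flags = pseudogene_flags or {}
    out: list[FamilyAssignment] = []
    for locus_id in sorted(domains):
        locus_domains = domains[locus_id]
        assigned = None
        for name in priority:
            rule = by_name[name]
            if rule.matches(locus_domains):
                assigned = rule
                break
        if assigned is None:
            logger.info("locus %s matched no family (domains: %s)", locus_id, sorted(locus_domains))
            continue
        signature = tuple(sorted(locus_domains - assigned.defining_domains - assigned.excluded_domains))
        out.append(
            FamilyAssignment(
                locus_id=locus_id,
                family_name=assigned.family_name,
                subfamily_signature=signature,
                is_pseudogene=bool(flags.get(locus_id, False)),
            )
        )
    return out


def subfamily_key(assignment: FamilyAssignment, mode: str = "family+signature"):
    """Hashable subfamily key for tandem testing and enrichment."""
    if mode == "family":
        return assignment.family_name
    return (assignment.family_name, assignment.subfamily_signature)


def family_size_table(
    assignments: Iterable[FamilyAssignment],
    species_of_locus: Mapping[str, str],
    families: Sequence[str] = UPS_FAMILIES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(total, pseudogene-excluded) species-by-family locus count matrices."""
    assignments = list(assignments)
    species = sorted(set(species_of_locus.values()))
    total = pd.DataFrame(0, index=species, columns=list(families))
    active = total.copy()
    for a in assignments:
        try:
            sp = species_of_locus[a.locus_id]
        except KeyError:
            raise KeyError(f"unknown species for locus {a.locus_id}") from None
        if a.family_name not in total.columns:
            total[a.family_name] = 0
            active[a.family_name] = 0
        total.loc[sp, a.family_name] += 1
        if not a.is_pseudogene:
            active.loc[sp, a.family_name] += 1
    return total, active
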