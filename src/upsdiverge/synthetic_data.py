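"""Synthetic multi-genome generator with planted ground truth.

Emulates the comparative setup of the UPS study: a focal species (the *Aly*
role) inside a ladder of nested within-family species sets, an
ancestral-angiosperm outgroup (*Atr* role) and a second plant-family clade
(the Poaceae role).  Gene families are seeded with ancestral orthogroups
(age rank A) and expanded by birth events placed on the ladder, so every
planted orthogroup has a known age rank, duplication mode (tandem /
retrocopy / dispersed), domain architecture, true pairwise omega and
coordinates — all recoverable by the downstream annotation, clustering,
duplication and selection stages.

Genes are laid on one chromosome per species at uniform spacing (default
30 kb start-to-start), with a buffer of unrelated background genes between
family loci so the tandem rule (≤10 intervening genes, ≤300 kb) is decided
by construction: planted tandem copies sit adjacent to their template;
everything else is separated by more than the thresholds.  Background genes
are real gene models in the emitted GFF3/FASTA (they set the gene order
index) but carry no UPS domains and are not part of the orthogroup
universe.

Coding sequences evolve under the GY94 codon model by exact
matrix-exponential sampling per codon along a star topology whose branch
lengths follow the ladder depth of each species; omega is set per age
class, declining with age as in the empirical trend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._codon import N_CODONS, CodonModel, decode_codons
from .duplication import GeneLocus
from .family_annotation import default_rules

DIVERGENCE_PER_STEP = 0.12  # expected substitutions/codon between adjacent ladder steps


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class LadderConfig:
    """Focal species plus strictly nested within-family species sets, an
    outgroup and the species of the other plant family."""

    focal_species: str
    nested_sets: tuple[tuple[str, ...], ...]
    outgroup_species: str
    second_family_species: tuple[str, ...] = ()
    rank_labels: tuple[str, ...] = ("6", "7", "8", "9", "10")
    seed: int = 0

    def __post_init__(self):
        if not self.focal_species or not self.nested_sets:
            raise ValueError("ladder needs a focal species and at least one nested set")
        prev: set[str] = set()
        for s in self.nested_sets:
            cur = set(s)
            if not prev < cur:
                raise ValueError("nested sets must be strictly increasing supersets")
            if self.focal_species in cur:
                raise ValueError("focal species must not appear in nested sets")
            prev = cur
        if len(self.rank_labels) != len(self.nested_sets):
            raise ValueError("one rank label per nested set required")
        names = self.all_species
        if len(names) != len(set(names)):
            raise ValueError("species names must be unique")

    @property
    def within_family_others(self) -> tuple[str, ...]:
        return self.nested_sets[-1]

    @property
    def all_species(self) -> tuple[str, ...]:
        return (
            self.focal_species,
            *self.within_family_others,
            self.outgroup_species,
            *self.second_family_species,
        )

    def depth(self, species: str) -> int:
        """Ladder distance from the focal species (outgroup/other family deepest)."""
        if species == self.focal_species:
            return 0
        for i, nested in enumerate(self.nested_sets):
            if species in nested:
                return i + 1
        return len(self.nested_sets) + 1


def brassicaceae_ladder(seed: int = 0, second_family: bool = True) -> LadderConfig:
    """The default six-plus-one species ladder (Aly focal, Atr outgroup)."""
    return LadderConfig(
        focal_species="Aly",
        nested_sets=(
            ("Aha",),
            ("Aha", "Ath"),
            ("Aha", "Ath", "Cru"),
            ("Aha", "Ath", "Cru", "Bst"),
            ("Aha", "Ath", "Cru", "Bst", "Bra"),
        ),
        outgroup_species="Atr",
        second_family_species=("Osa", "Obr", "Opu", "Lpe", "Sbi", "Bdi") if second_family else (),
        seed=seed,
    )


DEFAULT_ANCESTRAL_GROUPS: Mapping[str, int] = {
    "FBX": 6, "RING": 6, "BTB": 4, "E2": 4, "RP": 4, "CP": 4,
    "E1": 2, "Cullin": 2, "APC": 3, "HECT": 2, "Skp1": 2,
}

DEFAULT_OMEGA_BY_CLASS: Mapping[str, float] = {
    "0": 0.8, "6": 0.6, "7": 0.5, "8": 0.4, "9": 0.3, "10": 0.2,
    "A": 0.1, "second": 0.4,
}

ACCESSORY_DOMAIN_POOL = (
    "Kelch_1", "LRR_4", "FBA_1", "PP2", "Arm", "MATH", "BACK", "NPH3",
    "WD40", "TPR_1", "Ank_2", "DUF295",
)


@dataclass(frozen=True)
class EvolveParams:
    """Rates and sizes of the simulated family histories."""

    birth_rate: float = 0.4          # orthogroup births per family per age step
    death_rate: float = 0.0          # per-lineage loss probability per age step
    tandem_fraction: float = 0.6     # P(a birth is a tandem duplication)
    retro_fraction: float = 0.25     # P(a birth is an intronless retrocopy)
    kappa: float = 2.0
    omega_by_class: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_OMEGA_BY_CLASS))
    codon_length: int = 100
    seed: int = 0
    families: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_ANCESTRAL_GROUPS))
    birth_bias: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    gene_spacing_bp: int = 30_000
    background_genes: tuple[int, int] = (12, 20)  # buffer genes between family loci
    pseudogene_fraction: float = 0.05             # applied to young-rank loci
    intron_length_bp: int = 100
    accessory_gain_prob: float = 0.3

    def __post_init__(self):
        if self.birth_rate < 0 or self.death_rate < 0:
            raise ValueError("rates must be non-negative")
        for frac in (self.tandem_fraction, self.retro_fraction, self.pseudogene_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.tandem_fraction + self.retro_fraction > 1:
            raise ValueError("tandem_fraction + retro_fraction must not exceed 1")
        if any(w <= 0 for w in self.omega_by_class.values()):
            raise ValueError("omega values must be positive")
        if self.codon_length < 30:
            raise ValueError("codon_length must be at least 30")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


# ---------------------------------------------------------------------------
# ground truth container


@dataclass
class _Group:
    group_id: str
    family: str
    rank: str                      # "0", ladder labels, "A", or "second"
    presence: list[str]
    mode: str                      # ancestral | tandem | retro | dispersed
    template: str | None
    accessories: tuple[str, ...]
    defining: tuple[str, ...]
    born_step: int


@dataclass
class GenomeTruth:
    """Planted ground truth for one simulated multi-genome data set."""

    ladder: LadderConfig
    params: EvolveParams
    loci: dict[str, list[GeneLocus]]                      # per species, chromosome order
    cds: dict[str, str]
    domain_architecture: dict[str, tuple[tuple[str, int, int, float], ...]]
    family_of_locus: dict[str, str]
    group_of_locus: dict[str, str]
    true_orthogroups: dict[str, tuple[str, ...]]
    true_age_rank: dict[str, str]
    family_of_group: dict[str, str]
    subfamily_of_group: dict[str, tuple[str, ...]]
    duplication_mode: dict[str, str]                      # locus -> mode (background genes excluded)
    tandem_truth: dict[str, set[str]]                     # species -> loci in planted arrays
    true_omega: dict[tuple[str, str], float]

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.loci)

    def species_of_locus(self) -> dict[str, str]:
        return {locus.locus_id: sp for sp, ll in self.loci.items() for locus in ll}

    def family_loci(self, species: str) -> list[GeneLocus]:
        return [l for l in self.loci[species] if l.locus_id in self.family_of_locus]

    def subfamily_of_locus(self) -> dict[str, tuple[str, tuple[str, ...]]]:
        out = {}
        for locus_id, group_id in self.group_of_locus.items():
            out[locus_id] = (self.family_of_group[group_id], self.subfamily_of_group[group_id])
        return out

    def retro_truth(self, species: str) -> set[str]:
        return {
            l.locus_id
            for l in self.family_loci(species)
            if self.duplication_mode[l.locus_id] == "retro"
        }

    def validate(self) -> None:
        seen: set[str] = set()
        for members in self.true_orthogroups.values():
            for m in members:
                if m in seen:
                    raise AssertionError(f"locus {m} in two orthogroups")
                seen.add(m)
        if seen != set(self.family_of_locus):
            raise AssertionError("orthogroups do not partition the family loci")
        for locus_id, mode in self.duplication_mode.items():
            if mode == "retro":
                locus = self._locus(locus_id)
                if locus.intron_count != 0:
                    raise AssertionError(f"retro locus {locus_id} has introns")

    def _locus(self, locus_id: str) -> GeneLocus:
        for ll in self.loci.values():
            for l in ll:
                if l.locus_id == locus_id:
                    return l
        raise KeyError(locus_id)


# ---------------------------------------------------------------------------
# simulation


def _defining_combo(family: str) -> tuple[str, ...]:
    rules, _ = default_rules()
    for rule in rules:
        if rule.family_name == family:
            return tuple(sorted(rule.required_combinations[0]))
    raise KeyError(f"no shipped rule for family {family}")


def _draw_mode(rng: np.random.Generator, params: EvolveParams) -> str:
    u = rng.random()
    if u < params.tandem_fraction:
        return "tandem"
    if u < params.tandem_fraction + params.retro_fraction:
        return "retro"
    return "dispersed"


def _make_groups(ladder: LadderConfig, params: EvolveParams, rng: np.random.Generator) -> list[_Group]:
    all_species = list(ladder.all_species)
    second = list(ladder.second_family_species)
    n_steps = len(ladder.nested_sets) + 1
    serial = {f: 0 for f in params.families}
    groups: list[_Group] = []
    ancestral_by_family: dict[str, list[_Group]] = {f: [] for f in params.families}

    def new_id(family: str) -> str:
        serial[family] += 1
        return f"{family}{serial[family]:03d}"

    for family, count in params.families.items():
        defining = _defining_combo(family)
        for _ in range(count):
            n_acc = int(rng.integers(0, 3))
            accessories = tuple(sorted(rng.choice(ACCESSORY_DOMAIN_POOL, size=n_acc, replace=False)))
            g = _Group(
                group_id=new_id(family), family=family, rank="A",
                presence=list(all_species), mode="ancestral", template=None,
                accessories=accessories, defining=defining, born_step=0,
            )
            groups.append(g)
            ancestral_by_family[family].append(g)

    def spawn(family: str, rank: str, presence: list[str], step: int) -> None:
        templates = ancestral_by_family[family]
        if not templates:
            return
        template = templates[int(rng.integers(0, len(templates)))]
        mode = _draw_mode(rng, params)
        accessories = template.accessories
        # tandem copies keep the template architecture (same subfamily by
        # construction); other modes may gain an accessory domain
        if mode != "tandem" and rng.random() < params.accessory_gain_prob:
            extra = str(rng.choice(ACCESSORY_DOMAIN_POOL))
            accessories = tuple(sorted(set(accessories) | {extra}))
        groups.append(
            _Group(
                group_id=new_id(family), family=family, rank=rank,
                presence=list(presence), mode=mode,
                template=template.group_id, accessories=accessories,
                defining=template.defining, born_step=step,
            )
        )

    # focal-clade births: one age step per ladder rank plus the private rank 0;
    # the step value records how many age steps the lineage has existed
    focal_ranks: list[tuple[str, list[str], int]] = []
    for i, label in enumerate(ladder.rank_labels):
        focal_ranks.append((label, [ladder.focal_species, *ladder.nested_sets[i]], i + 1))
    focal_ranks.append(("0", [ladder.focal_species], 0))
    for family in params.families:
        bias_focal, bias_second = params.birth_bias.get(family, (1.0, 1.0))
        for label, presence, step in focal_ranks:
            for _ in range(rng.poisson(params.birth_rate * bias_focal)):
                spawn(family, label, presence, step)
        if second:
            for step in range(n_steps):
                for _ in range(rng.poisson(params.birth_rate * bias_second)):
                    spawn(family, "second", list(second), step)
    return groups


def _apply_death(groups: list[_Group], ladder: LadderConfig, params: EvolveParams,
                 rng: np.random.Generator) -> list[_Group]:
    if params.death_rate == 0:
        return groups
    n_steps = len(ladder.nested_sets) + 1
    surviving: list[_Group] = []
    for g in groups:
        steps_alive = n_steps if g.rank in ("A", "second") else g.born_step
        p_loss = 1.0 - (1.0 - params.death_rate) ** steps_alive
        g.presence = [sp for sp in g.presence if rng.random() >= p_loss]
        if g.presence:
            surviving.append(g)
    for family in params.families:
        if not any(g.family == family for g in surviving):
            raise SimulationError(f"family {family} lost all members (death_rate too high)")
    return surviving


def _evolve_group_sequences(
    group: _Group, ladder: LadderConfig, params: EvolveParams, rng: np.random.Generator,
    model_cache: dict, prob_cache: dict,
) -> dict[str, np.ndarray]:
    omega = _omega_for_rank(group.rank, params)
    key = round(omega, 12)
    if key not in model_cache:
        model_cache[key] = CodonModel.build(params.kappa, omega)
    model = model_cache[key]
    length = params.codon_length
    ancestor = rng.integers(0, N_CODONS, size=length)
    out: dict[str, np.ndarray] = {}
    for sp in group.presence:
        depth = max(ladder.depth(sp), 1)
        branch = DIVERGENCE_PER_STEP * (depth + 1) / 2.0
        pkey = (key, round(branch, 12))
        if pkey not in prob_cache:
            prob_cache[pkey] = np.cumsum(model.transition_probs(branch), axis=1)
        cum = prob_cache[pkey]
        u = rng.random(length)
        child = np.empty(length, dtype=np.int64)
        for i, (anc, ui) in enumerate(zip(ancestor, u)):
            child[i] = np.searchsorted(cum[anc], ui, side="right")
        np.clip(child, 0, N_CODONS - 1, out=child)
        out[sp] = child
    return out


def _omega_for_rank(rank: str, params: EvolveParams) -> float:
    try:
        return float(params.omega_by_class[rank])
    except KeyError:
        raise SimulationError(f"omega_by_class has no entry for age class {rank!r}") from None


def simulate_genomes(ladder: LadderConfig, params: EvolveParams) -> GenomeTruth:
    """Simulate the full multi-genome data set; deterministic per seeds."""
    if not ladder.all_species:
        raise SimulationError("no species to simulate")
    rng = np.random.default_rng([ladder.seed & 0x7FFFFFFF, params.seed & 0x7FFFFFFF])
    groups = _make_groups(ladder, params, rng)
    groups = _apply_death(groups, ladder, params, rng)
    by_id = {g.group_id: g for g in groups}

    model_cache: dict = {}
    prob_cache: dict = {}
    seqs: dict[str, dict[str, np.ndarray]] = {
        g.group_id: _evolve_group_sequences(g, ladder, params, rng, model_cache, prob_cache)
        for g in groups
    }

    young_ranks = {"0", ladder.rank_labels[0]}
    cds: dict[str, str] = {}
    loci: dict[str, list[GeneLocus]] = {}
    family_of_locus: dict[str, str] = {}
    group_of_locus: dict[str, str] = {}
    duplication_mode: dict[str, str] = {}
    tandem_truth: dict[str, set[str]] = {}
    domain_architecture: dict[str, tuple[tuple[str, int, int, float], ...]] = {}
    members_by_group: dict[str, list[str]] = {g.group_id: [] for g in groups}

    for sp in ladder.all_species:
        present = [g for g in groups if sp in g.presence]
        tandem_children: dict[str, list[_Group]] = {}
        singles: list[_Group] = []
        for g in present:
            if g.mode == "tandem" and g.template is not None and sp in by_id[g.template].presence:
                tandem_children.setdefault(g.template, []).append(g)
            else:
                singles.append(g)
        order = [singles[i] for i in rng.permutation(len(singles))]

        slots: list[tuple[str, _Group | None]] = []  # (kind, group)
        arrays: list[list[str]] = []
        for g in order:
            for _ in range(int(rng.integers(params.background_genes[0], params.background_genes[1] + 1))):
                slots.append(("background", None))
            slots.append(("family", g))
            children = sorted(tandem_children.get(g.group_id, []), key=lambda c: c.group_id)
            if children:
                arrays.append([g.group_id] + [c.group_id for c in children])
                for c in children:
                    slots.append(("family", c))
        for _ in range(int(rng.integers(params.background_genes[0], params.background_genes[1] + 1))):
            slots.append(("background", None))

        species_loci: list[GeneLocus] = []
        bg_serial = 0
        array_locus_ids: set[str] = set()
        array_groups = {gid for arr in arrays for gid in arr}
        for idx, (kind, g) in enumerate(slots):
            start = 1 + idx * params.gene_spacing_bp
            if kind == "background":
                bg_serial += 1
                locus_id = f"{sp}|BG{bg_serial:04d}"
                introns = int(rng.integers(0, 5))
                seq_idx = rng.integers(0, N_CODONS, size=params.codon_length)
            else:
                locus_id = f"{sp}|{g.group_id}"
                introns = 0 if g.mode == "retro" else int(rng.integers(1, 6))
                seq_idx = seqs[g.group_id][sp]
            cds_len = 3 * params.codon_length
            end = start + cds_len + introns * params.intron_length_bp - 1
            pseudo = False
            if kind == "family":
                if g.rank in young_ranks and rng.random() < params.pseudogene_fraction:
                    pseudo = True
            locus = GeneLocus(
                locus_id=locus_id, species=sp, chromosome=f"{sp}_chr1",
                start=start, end=end, strand="+" if rng.random() < 0.5 else "-",
                order_index=idx + 1, intron_count=introns, is_pseudogene=pseudo,
            )
            species_loci.append(locus)
            cds[locus_id] = decode_codons(seq_idx)
            if kind == "family":
                family_of_locus[locus_id] = g.family
                group_of_locus[locus_id] = g.group_id
                duplication_mode[locus_id] = g.mode
                members_by_group[g.group_id].append(locus_id)
                if g.group_id in array_groups:
                    array_locus_ids.add(locus_id)
                domains = list(g.defining) + list(g.accessories)
                hits = []
                pos = 1
                for d in domains:
                    span = max(10, params.codon_length // (len(domains) + 1))
                    hits.append((d, pos, min(pos + span - 1, params.codon_length),
                                 float(10.0 ** -rng.uniform(5, 50))))
                    pos += span
                # occasional weak decoy hit above the E-value cutoff
                if rng.random() < 0.1:
                    decoy = str(rng.choice(ACCESSORY_DOMAIN_POOL))
                    hits.append((decoy, 1, 10, float(rng.uniform(1.5, 5.0))))
                domain_architecture[locus_id] = tuple(hits)
        tandem_truth[sp] = array_locus_ids
        loci[sp] = species_loci

    true_orthogroups = {
        gid: tuple(members) for gid, members in members_by_group.items() if members
    }
    true_age_rank = {}
    for g in groups:
        if g.group_id not in true_orthogroups:
            continue
        if ladder.focal_species in g.presence:
            true_age_rank[g.group_id] = g.rank if g.rank != "second" else "non_ranked"
        else:
            true_age_rank[g.group_id] = "not_applicable"

    true_omega: dict[tuple[str, str], float] = {}
    for g in groups:
        if g.group_id not in true_orthogroups:
            continue
        omega = _omega_for_rank(g.rank, params)
        anchor = ladder.focal_species if ladder.focal_species in g.presence else (
            ladder.second_family_species[0]
            if ladder.second_family_species and ladder.second_family_species[0] in g.presence
            else None
        )
        if anchor is None:
            continue
        for sp in g.presence:
            if sp == anchor:
                continue
            true_omega[(f"{anchor}|{g.group_id}", f"{sp}|{g.group_id}")] = omega

    truth = GenomeTruth(
        ladder=ladder, params=params, loci=loci, cds=cds,
        domain_architecture=domain_architecture, family_of_locus=family_of_locus,
        group_of_locus=group_of_locus, true_orthogroups=true_orthogroups,
        true_age_rank=true_age_rank,
        family_of_group={g.group_id: g.family for g in groups if g.group_id in true_orthogroups},
        subfamily_of_group={g.group_id: g.accessories for g in groups if g.group_id in true_orthogroups},
        duplication_mode=duplication_mode, tandem_truth=tandem_truth, true_omega=true_omega,
    )
    truth.validate()
    return truth


# ---------------------------------------------------------------------------
# pairwise codon simulator


def evolve_codon_pair(
    length_codons: int, t: float, kappa: float, omega: float, seed: int
) -> tuple[str, str]:
    """Two coding sequences diverged by ``t`` expected substitutions per
    codon under the GY94 model (each lineage evolved t/2 from a uniform
    ancestor); never contains stop codons, identical at t = 0."""
    if length_codons < 1:
        raise ValueError("length must be at least 1 codon")
    if t < 0 or kappa <= 0 or omega <= 0:
        raise ValueError("t must be non-negative; kappa and omega positive")
    rng = np.random.default_rng(seed)
    ancestor = rng.integers(0, N_CODONS, size=length_codons)
    if t == 0:
        seq = decode_codons(ancestor)
        return seq, seq
    model = CodonModel.build(kappa, omega)
    cum = np.cumsum(model.transition_probs(t / 2.0), axis=1)
    out = []
    for _ in range(2):
        u = rng.random(length_codons)
        child = np.empty(length_codons, dtype=np.int64)
        for i, (anc, ui) in enumerate(zip(ancestor, u)):
            child[i] = np.searchsorted(cum[anc], ui, side="right")
        np.clip(child, 0, N_CODONS - 1, out=child)
        out.append(decode_codons(child))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# planted similarity graph (clustering benchmarks)


def planted_similarity_graph(
    n_families: int = 20,
    per_family: int = 6,
    within_weight: tuple[float, float] = (60.0, 100.0),
    between_weight: tuple[float, float] = (1.0, 8.0),
    between_prob: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Similarity rows for a planted-partition graph: dense strong edges
    within each family, sparse weak edges between.  Returns (rows, truth
    labels)."""
    rng = np.random.default_rng(seed)
    nodes = [
        (f"S{j}|fam{f:02d}", f)
        for f in range(n_families)
        for j in range(per_family)
    ]
    labels = dict(nodes)
    rows = []
    ids = [n for n, _ in nodes]
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            same = labels[a] == labels[b]
            if same:
                w = rng.uniform(*within_weight)
            elif rng.random() < between_prob:
                w = rng.uniform(*between_weight)
            else:
                continue
            rows.append(
                {"qseqid": a, "sseqid": b, "pident": w, "length": 100,
                 "score": w, "evalue": 10.0 ** (-w)}
            )
    return pd.DataFrame(rows), labels


# ---------------------------------------------------------------------------
# file emission


def _translate(cds: str) -> str:
    return str(Seq(cds).translate())


def _exon_spans(start: int, cds_len: int, introns: int, intron_len: int) -> list[tuple[int, int]]:
    n_exons = introns + 1
    base = cds_len // n_exons
    sizes = [base] * n_exons
    sizes[-1] += cds_len - base * n_exons
    spans = []
    pos = start
    for size in sizes:
        spans.append((pos, pos + size - 1))
        pos += size + intron_len
    return spans


def emit_files(truth: GenomeTruth, out_dir) -> dict[str, Path]:
    """Write per-species CDS/protein FASTA, GFF3 and domain-hit tables, the
    all-vs-all similarity table, and the ground-truth TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    params = truth.params

    for sp, species_loci in truth.loci.items():
        cds_records, pep_records, gff_lines, hit_rows = [], [], ["##gff-version 3"], []
        for locus in species_loci:
            seq = truth.cds[locus.locus_id]
            if len(seq) % 3:
                raise ValueError(f"{locus.locus_id}: CDS length not a multiple of 3")
            cds_records.append(SeqRecord(Seq(seq), id=locus.locus_id, description=""))
            pep_records.append(SeqRecord(Seq(_translate(seq)), id=locus.locus_id, description=""))
            chrom, s0, strand = locus.chromosome, locus.start, locus.strand
            mrna_id = f"{locus.locus_id}.1"
            gff_lines.append(
                f"{chrom}\tupsdiverge\tgene\t{s0}\t{locus.end}\t.\t{strand}\t.\tID={locus.locus_id}"
            )
            gff_lines.append(
                f"{chrom}\tupsdiverge\tmRNA\t{s0}\t{locus.end}\t.\t{strand}\t.\tID={mrna_id};Parent={locus.locus_id}"
            )
            for es, ee in _exon_spans(s0, len(seq), locus.intron_count, params.intron_length_bp):
                gff_lines.append(f"{chrom}\tupsdiverge\texon\t{es}\t{ee}\t.\t{strand}\t.\tParent={mrna_id}")
                gff_lines.append(f"{chrom}\tupsdiverge\tCDS\t{es}\t{ee}\t.\t{strand}\t0\tParent={mrna_id}")
            for domain, ds, de, evalue in truth.domain_architecture.get(locus.locus_id, ()):
                hit_rows.append((locus.locus_id, domain, evalue, ds, de))
        paths[f"{sp}.cds"] = out / f"{sp}.cds.fasta"
        SeqIO.write(cds_records, paths[f"{sp}.cds"], "fasta")
        paths[f"{sp}.pep"] = out / f"{sp}.pep.fasta"
        SeqIO.write(pep_records, paths[f"{sp}.pep"], "fasta")
        paths[f"{sp}.gff3"] = out / f"{sp}.gff3"
        paths[f"{sp}.gff3"].write_text("\n".join(gff_lines) + "\n")
        paths[f"{sp}.domains"] = out / f"{sp}.domains.tsv"
        pd.DataFrame(hit_rows, columns=["locus", "domain", "evalue", "start", "end"]).to_csv(
            paths[f"{sp}.domains"], sep="\t", index=False
        )

    paths["similarity"] = out / "similarity.tsv"
    similarity_table(truth).to_csv(paths["similarity"], sep="\t", index=False)

    truth_rows = []
    species_of = truth.species_of_locus()
    pseudo = {l.locus_id: l.is_pseudogene for ll in truth.loci.values() for l in ll}
    for locus_id, group_id in truth.group_of_locus.items():
        truth_rows.append(
            {
                "locus": locus_id,
                "species": species_of[locus_id],
                "group_id": group_id,
                "family": truth.family_of_locus[locus_id],
                "age_rank": truth.true_age_rank[group_id],
                "duplication_mode": truth.duplication_mode[locus_id],
                "tandem_truth": locus_id in truth.tandem_truth[species_of[locus_id]],
                "is_pseudogene": pseudo[locus_id],
            }
        )
    paths["truth_loci"] = out / "truth_loci.tsv"
    pd.DataFrame(truth_rows).to_csv(paths["truth_loci"], sep="\t", index=False)
    paths["truth_pairs"] = out / "truth_pairs.tsv"
    pd.DataFrame(
        [{"locus_a": a, "locus_b": b, "omega": w} for (a, b), w in truth.true_omega.items()]
    ).to_csv(paths["truth_pairs"], sep="\t", index=False)
    return paths


def similarity_table(truth: GenomeTruth, report_min_pident: float = 30.0) -> pd.DataFrame:
    """All-vs-all similarity rows from ungapped pairwise protein identity of
    equal-length family members.

    Pairs below ``report_min_pident`` are omitted, mimicking a search tool's
    reporting threshold: cross-family pairs and unrelated same-family pairs
    (independent ancestral sequences, ~6% background identity) fall below
    it, while within-orthogroup pairs stay far above.
    """
    by_family: dict[str, list[str]] = {}
    for locus_id, family in truth.family_of_locus.items():
        by_family.setdefault(family, []).append(locus_id)
    rows = []
    for family in sorted(by_family):
        ids = sorted(by_family[family])
        prots = [np.frombuffer(_translate(truth.cds[i]).encode(), dtype="S1") for i in ids]
        length = len(prots[0])
        mat = np.stack(prots)
        for i in range(len(ids)):
            same = (mat[i + 1 :] == mat[i]).mean(axis=1)
            for off, frac in enumerate(same):
                j = i + 1 + off
                if frac * 100.0 < report_min_pident:
                    continue
                score = float(frac * length)
                evalue = 10.0 ** (-min(score, 180.0))
                rows.append(
                    {
                        "qseqid": ids[i], "sseqid": ids[j],
                        "pident": round(float(frac) * 100.0, 2),
                        "length": length, "score": round(score, 2), "evalue": evalue,
                    }
                )
    return pd.DataFrame(rows, columns=["qseqid", "sseqid", "pident", "length", "score", "evalue"])
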