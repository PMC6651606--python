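"""Recent-duplication classification: tandem arrays and intronless retrocopies.

Two genes are called tandem duplicates when they belong to the same
subfamily, sit on the same chromosome separated by at most a configurable
number of intervening genes (default 10, counted against the full gene
complement) and lie within a maximum genomic distance (default 300 kb,
measured end-of-upstream to start-of-downstream).  A locus is called
intronless — the working proxy for retrotransposition — when its
representative transcript (longest CDS) has a single exon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

GFF_COLUMNS = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]


@dataclass
class GeneLocus:
    """One annotated gene model."""

    locus_id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str
    order_index: int | None
    intron_count: int
    is_pseudogene: bool = False

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.locus_id}: start > end")
        if self.intron_count < 0:
            raise ValueError(f"{self.locus_id}: negative intron count")


@dataclass(frozen=True)
class DupConfig:
    max_intervening_genes: int = 10
    max_distance_bp: int = 300_000
    subfamily_mode: Literal["family", "family+signature"] = "family+signature"

    def __post_init__(self):
        if self.max_intervening_genes <= 0 or self.max_distance_bp <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class DuplicationCall:
    locus_id: str
    tandem: bool
    intronless: bool
    tandem_partner: str | None = None

    def __post_init__(self):
        if self.tandem and self.tandem_partner is None:
            raise ValueError("tandem call requires a partner")


def classify_tandem(
    loci: Iterable[GeneLocus],
    subfamily_of_locus: Mapping[str, object],
    config: DupConfig = DupConfig(),
) -> list[DuplicationCall]:
    """Flag tandem duplicates among ``loci``.

    ``subfamily_of_locus`` maps locus ids to a hashable subfamily key (family
    name, or family plus accessory-domain signature); loci missing from the
    mapping are never tandem.  The relation is symmetric: both members of a
    qualifying pair are flagged, the recorded partner being the nearest
    qualifying neighbor.  order_index must be present on every locus and must
    rank the gene among the full gene complement of its chromosome.
    """
    loci = list(loci)
    for locus in loci:
        if locus.order_index is None:
            raise ValueError(f"{locus.locus_id}: missing order_index")
    groups: dict[tuple, list[GeneLocus]] = {}
    for locus in loci:
        key = subfamily_of_locus.get(locus.locus_id)
        if key is None:
            continue
        groups.setdefault((locus.species, locus.chromosome, key), []).append(locus)

    partner: dict[str, tuple[int, str]] = {}  # locus -> (index gap, partner id)
    max_index_gap = config.max_intervening_genes + 1
    for members in groups.values():
        members.sort(key=lambda g: g.order_index)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                gap_genes = b.order_index - a.order_index
                if gap_genes > max_index_gap:
                    break
                upstream, downstream = (a, b) if a.start <= b.start else (b, a)
                if downstream.start - upstream.end > config.max_distance_bp:
                    continue
                for x, y in ((a, b), (b, a)):
                    best = partner.get(x.locus_id)
                    if best is None or gap_genes < best[0]:
                        partner[x.locus_id] = (gap_genes, y.locus_id)
    return [
        DuplicationCall(
            locus_id=locus.locus_id,
            tandem=locus.locus_id in partner,
            intronless=locus.intron_count == 0,
            tandem_partner=partner[locus.locus_id][1] if locus.locus_id in partner else None,
        )
        for locus in loci
    ]


# ---------------------------------------------------------------------------
# GFF3 handling


def _parse_attributes(attr: str) -> dict[str, str]:
    out = {}
    for item in attr.strip().strip(";").split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=GFF_COLUMNS,
                     dtype={"seqid": str, "type": str, "attributes": str})
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def _transcript_tables(gff: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, str], dict[str, list]]:
    """(gene rows, transcript->gene, transcript->exon rows)."""
    genes = gff[gff["type"] == "gene"].copy()
    mrnas = gff[gff["type"].isin(["mRNA", "transcript"])]
    tx_gene: dict[str, str] = {}
    for _, row in mrnas.iterrows():
        attrs = _parse_attributes(row["attributes"])
        tx_gene[attrs["ID"]] = attrs.get("Parent", attrs["ID"])
    tx_exons: dict[str, list] = {tx: [] for tx in tx_gene}
    tx_cds_len: dict[str, int] = {tx: 0 for tx in tx_gene}
    for _, row in gff[gff["type"].isin(["exon", "CDS"])].iterrows():
        attrs = _parse_attributes(row["attributes"])
        parents = attrs.get("Parent", "").split(",")
        for parent in parents:
            if parent not in tx_gene:
                continue
            if row["type"] == "exon":
                tx_exons[parent].append((row["start"], row["end"]))
            else:
                tx_cds_len[parent] += row["end"] - row["start"] + 1
    return genes, tx_gene, {"exons": tx_exons, "cds_len": tx_cds_len}  # type: ignore[return-value]


def classify_intronless(
    gff_models: pd.DataFrame | str,
    representative: Literal["longest_cds"] = "longest_cds",
) -> dict[str, bool]:
    """Intronless flags per gene from GFF3 exon structure.

    The representative transcript of a locus is the one with the longest
    total CDS; the locus is intronless iff that transcript has exactly one
    exon.  A gene whose transcripts carry no exon features raises.
    """
    gff = read_gff3(gff_models) if not isinstance(gff_models, pd.DataFrame) else gff_models
    genes, tx_gene, tables = _transcript_tables(gff)
    by_gene: dict[str, list[str]] = {}
    for tx, gene in tx_gene.items():
        by_gene.setdefault(gene, []).append(tx)
    out: dict[str, bool] = {}
    for _, row in genes.iterrows():
        gene_id = _parse_attributes(row["attributes"])["ID"]
        txs = by_gene.get(gene_id, [])
        exonful = [tx for tx in txs if tables["exons"][tx]]
        if not exonful:
            raise ValueError(f"locus {gene_id} has no exon features")
        rep = max(exonful, key=lambda tx: (tables["cds_len"][tx], tx))
        out[gene_id] = len(tables["exons"][rep]) == 1
    return out


def loci_from_gff(gff_models: pd.DataFrame | str, species: str,
                  pseudogene_flags: Mapping[str, bool] | None = None) -> list[GeneLocus]:
    """Gene loci with chromosome order ranks and representative intron counts."""
    gff = read_gff3(gff_models) if not isinstance(gff_models, pd.DataFrame) else gff_models
    genes, tx_gene, tables = _transcript_tables(gff)
    by_gene: dict[str, list[str]] = {}
    for tx, gene in tx_gene.items():
        by_gene.setdefault(gene, []).append(tx)
    records = []
    for _, row in genes.iterrows():
        attrs = _parse_attributes(row["attributes"])
        gene_id = attrs["ID"]
        txs = [tx for tx in by_gene.get(gene_id, []) if tables["exons"][tx]]
        if not txs:
            raise ValueError(f"locus {gene_id} has no exon features")
        rep = max(txs, key=lambda tx: (tables["cds_len"][tx], tx))
        records.append(
            dict(locus_id=gene_id, chromosome=row["seqid"], start=row["start"],
                 end=row["end"], strand=row["strand"],
                 intron_count=len(tables["exons"][rep]) - 1,
                 is_pseudogene=bool(pseudogene_flags.get(gene_id, False)) if pseudogene_flags else False)
        )
    records.sort(key=lambda r: (r["chromosome"], r["start"], r["locus_id"]))
    loci = []
    order: dict[str, int] = {}
    for rec in records:
        order[rec["chromosome"]] = order.get(rec["chromosome"], 0) + 1
        loci.append(GeneLocus(species=species, order_index=order[rec["chromosome"]], **rec))
    return loci


# ---------------------------------------------------------------------------
# enrichment


def duplication_enrichment(
    calls_a: Iterable[DuplicationCall],
    calls_b: Iterable[DuplicationCall],
    attribute: Literal["tandem", "intronless"] = "tandem",
) -> tuple[np.ndarray, float]:
    """2x2 Fisher exact test (two-sided) comparing the rate of tandem (or
    intronless) loci between two genomes for one family.

    Rows are genomes, columns are (positive, negative) counts; returns the
    table and the exact hypergeometric p-value.
    """
    table = np.zeros((2, 2), dtype=int)
    for row, calls in enumerate((list(calls_a), list(calls_b))):
        if not calls:
            raise ValueError("empty family in one of the genomes")
        for call in calls:
            flag = getattr(call, attribute)
            table[row, 0 if flag else 1] += 1
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(p)
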