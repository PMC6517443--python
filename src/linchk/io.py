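"""Readers and writers for every on-disk format the pipeline touches.

All genomic coordinates are converted to 0-based half-open at this
boundary (GTF is 1-based inclusive on disk). Each reader has a matching
writer and the pair round-trips exactly; auxiliary evidence tables
(probe betas, SNP positions, conservation scores, repeats, CNA
categories, focal regions, survival records) are dialect-checked
TSV/BED-like files with the column contracts documented per function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import obonet
import pandas as pd

from .core import ExpressionMatrix, GeneAnnotation, GenomicInterval


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path: str | Path, dialect: str = "gtf") -> list[GeneAnnotation]:
    """Read gene models from GTF (Ensembl dialect) or BED12.

    GTF ``exon`` features are grouped by ``gene_id``; ``gene_biotype``
    (or ``gene_type``) attributes are mapped onto
    {protein_coding, lincRNA, other}. Genes with no exons are rejected.
    """
    if dialect == "gtf":
        return _read_gtf(Path(path))
    if dialect == "bed12":
        return _read_bed12(Path(path))
    raise ValueError(f"unknown dialect {dialect!r}")


def _norm_biotype(bt: str) -> str:
    if bt in ("protein_coding", "lincRNA"):
        return bt
    return "other"


def _read_gtf(path: Path) -> list[GeneAnnotation]:
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ParseError(f"{path}:{ln}: expected 9 GTF columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = parts[:9]
            if feature != "exon":
                continue
            if strand not in ("+", "-", "."):
                raise ParseError(f"{path}:{ln}: unknown strand {strand!r}")
            start_i, end_i = int(start), int(end)
            if start_i < 1:
                raise ParseError(f"{path}:{ln}: GTF coordinates are 1-based; start={start_i}")
            attr = dict(
                (m.split(" ", 1)[0], m.split(" ", 1)[1].strip('"'))
                for m in (a.strip() for a in attrs.rstrip(";").split(";"))
                if " " in m
            )
            if "gene_id" not in attr:
                raise ParseError(f"{path}:{ln}: missing gene_id attribute")
            gid = attr["gene_id"]
            bt = attr.get("gene_biotype", attr.get("gene_type", "other"))
            rec = genes.setdefault(gid, {"biotype": _norm_biotype(bt), "strand": strand, "exons": []})
            # 1-based inclusive -> 0-based half-open
            rec["exons"].append(GenomicInterval(chrom, start_i - 1, end_i, strand))
    return [
        GeneAnnotation(gid, rec["biotype"], rec["strand"], rec["exons"])
        for gid, rec in genes.items()
    ]


def write_gtf(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            for iv in g.exons:
                attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
                fh.write(
                    f"{iv.chrom}\tlinchk\texon\t{iv.start + 1}\t{iv.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def _read_bed12(path: Path) -> list[GeneAnnotation]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}:{ln}: expected 12 BED columns")
            chrom, start, _end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            if start < 0:
                raise ParseError(f"{path}:{ln}: negative start")
            if strand not in ("+", "-", "."):
                raise ParseError(f"{path}:{ln}: unknown strand {strand!r}")
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ParseError(f"{path}:{ln}: blockCount mismatch")
            exons = [
                GenomicInterval(chrom, start + bs, start + bs + sz, strand)
                for bs, sz in zip(starts, sizes)
            ]
            out.append(GeneAnnotation(name, "other", strand, exons))
    return out


# ---------------------------------------------------------------------------
# expression matrices


def read_matrix(
    path: str | Path, tissue_of_sample: dict[str, str] | None = None, na_policy: str = "reject"
) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids).

    When ``tissue_of_sample`` is None each sample is its own tissue
    (one-sample-per-tissue layout). ``na_policy``: 'reject' or 'zero'.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"duplicate gene id {dup!r} in {path}")
    if df.isna().any().any():
        if na_policy == "zero":
            df = df.fillna(0.0)
        else:
            raise ParseError(f"NA values in {path} (na_policy=reject)")
    if (df.to_numpy(dtype=float) < 0).any():
        raise ParseError(f"negative expression values in {path}")
    if tissue_of_sample is None:
        tissue_of_sample = {s: s for s in df.columns}
    return ExpressionMatrix(df, tissue_of_sample)


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """id -> uppercase sequence over {A,C,G,T,N}; U mapped to T."""
    seqs, _ = read_fasta_with_masks(path)
    return seqs


def read_fasta_with_masks(path: str | Path) -> tuple[dict[str, str], dict[str, bool]]:
    """As read_fasta, plus a per-record soft-mask flag (any lowercase seen)."""
    seqs: dict[str, list[str]] = {}
    masked: dict[str, bool] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                if name in seqs:
                    raise ParseError(f"duplicate FASTA record {name!r}")
                seqs[name] = []
                masked[name] = False
            else:
                if name is None:
                    raise ParseError("sequence data before first FASTA header")
                if any(c.islower() for c in line):
                    masked[name] = True
                seqs[name].append(line.upper().replace("U", "T"))
    out = {k: "".join(v) for k, v in seqs.items()}
    for k, s in out.items():
        bad = set(s) - set("ACGTN")
        if bad:
            raise ParseError(f"record {k!r}: non-ACGTN characters {sorted(bad)}")
    return out, masked


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# gene sets and ontology


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style): name -> (description, set of gene ids)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    import warnings

    coll = GeneSetCollection()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3 or not any(g for g in f[2:]):
                warnings.warn(f"{path}:{ln}: empty gene set line rejected")
                continue
            name, desc = f[0], f[1]
            if name in coll.sets:
                raise ParseError(f"{path}:{ln}: duplicate gene set name {name!r}")
            coll.sets[name] = (desc, frozenset(g for g in f[2:] if g))
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in coll.sets.items():
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


@dataclass
class OntologyDAG:
    """Lightweight GO-like DAG: child -> [(parent, relation)] edges."""

    parents: dict[str, list[tuple[str, str]]]
    names: dict[str, str]

    def terms(self) -> list[str]:
        return list(self.parents)

    def ancestors(self, term: str) -> set[str]:
        out: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            for p, _rel in self.parents.get(t, ()):
                if p not in out:
                    out.add(p)
                    stack.append(p)
        return out


def read_obo_subset(path: str | Path) -> OntologyDAG:
    """Parse an OBO subset (id, name, is_a, relationship: part_of) via obonet."""
    graph = obonet.read_obo(path)
    if not nx.is_directed_acyclic_graph(graph):
        raise ParseError(f"cycle detected in ontology {path}")
    parents: dict[str, list[tuple[str, str]]] = {}
    names: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        parents.setdefault(node, [])
        names[node] = data.get("name", node)
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents[child].append((parent, "is_a"))
        elif key == "part_of":
            parents[child].append((parent, "part_of"))
    return OntologyDAG(parents, names)


def write_obo_subset(dag: OntologyDAG, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n\n")
        for term in dag.terms():
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {dag.names.get(term, term)}\n")
            for parent, rel in dag.parents.get(term, ()):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: part_of {parent}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# BED-like and evidence tables


def read_bed_intervals(path: str | Path, name_field: bool = False):
    """BED3 (intervals) or BED6 (name in column 4 kept, e.g. repeat class).

    Returns list[GenomicInterval] or list[(GenomicInterval, name)].
    """
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{ln}: expected >=3 BED columns")
            strand = f[5] if len(f) >= 6 else "."
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]), strand)
            if name_field:
                if len(f) < 4:
                    raise ParseError(f"{path}:{ln}: name column required")
                out.append((iv, f[3]))
            else:
                out.append(iv)
    return out


def write_bed_intervals(items, path: str | Path) -> None:
    """Write BED3 from intervals, or BED6 from (interval, name) pairs."""
    with open(path, "w") as fh:
        for item in items:
            if isinstance(item, tuple):
                iv, name = item
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{item.chrom}\t{item.start}\t{item.end}\n")


def read_score_table(path: str | Path) -> dict[tuple[str, int], float]:
    """Per-base scores: TSV with columns (chrom, pos0, score)."""
    out: dict[tuple[str, int], float] = {}
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "score"])
    for chrom, pos, score in df.itertuples(index=False):
        out[(str(chrom), int(pos))] = float(score)
    return out


def write_score_table(scores: dict[tuple[str, int], float], path: str | Path) -> None:
    with open(path, "w") as fh:
        for (chrom, pos), score in scores.items():
            fh.write(f"{chrom}\t{pos}\t{score}\n")


_DE_COLS = ["gene_id", "tumour_type", "log2_fc", "q"]


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Differential-expression table: gene_id, tumour_type, log2_fc, q."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _DE_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing DE columns {missing}")
    return df[_DE_COLS]


def read_cna_table(path: str | Path) -> pd.DataFrame:
    """Gene x sample copy-number category table (homdel/hetloss/diploid/gain/amp)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    valid = {"homdel", "hetloss", "diploid", "gain", "amp"}
    bad = set(pd.unique(df.values.ravel())) - valid
    if bad:
        raise ParseError(f"{path}: unknown CNA categories {sorted(bad)}")
    return df


def read_focal_regions(path: str | Path) -> list[tuple[GenomicInterval, str, str]]:
    """Focal alteration regions: chrom, start, end, region_id, type {amp,del}."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 5:
                raise ParseError(f"{path}:{ln}: expected 5 columns")
            if f[4] not in ("amp", "del"):
                raise ParseError(f"{path}:{ln}: region type must be amp|del")
            out.append((GenomicInterval(f[0], int(f[1]), int(f[2])), f[3], f[4]))
    return out


def read_probe_table(path: str | Path) -> pd.DataFrame:
    """Probe x sample methylation beta table; betas must lie in [0, 1]."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy(dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ParseError(f"{path}: beta values outside [0, 1]")
    return df


def read_survival_table(path: str | Path) -> pd.DataFrame:
    """Survival records: patient_id, time (>0), event {0,1}, expression."""
    df = pd.read_csv(path, sep="\t")
    need = ["patient_id", "time", "event"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing survival columns {missing}")
    if (df["time"] <= 0).any():
        raise ParseError(f"{path}: nonpositive survival times")
    if not set(df["event"]).issubset({0, 1}):
        raise ParseError(f"{path}: event must be 0 (censored) or 1 (death)")
    return df
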