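"""Readers and writers for every on-disk format the pipeline touches.

All genomic intervals are handled internally as 0-based half-open
``[start, end)``; the GFF3 1-based inclusive convention exists only at the
file boundary (:func:`read_gff3` / :func:`write_gff3`).  Tables are TSV
throughout.  Readers validate and reject malformed input rather than
silently coercing it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

ROLES = ("mRNA", "TF", "lncRNA", "miRNA")
UNITS = ("raw_count", "FPKM", "TPM", "log2")

#: GFF3 feature types mapped into the annotation; anything else is skipped
#: with a logged warning.
_GENE_TYPES = {"gene"}
_TRANSCRIPT_TYPES = {"mRNA", "transcript", "lnc_RNA", "lncRNA"}
_EXON_TYPES = {"exon"}


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass
class FeatureModel:
    """A gene or transcript with 0-based half-open coordinates.

    ``exons`` are sorted, non-overlapping ``(start, end)`` intervals within
    the feature span.  ``role`` is one of mRNA / TF / lncRNA (miRNAs are
    sequence-only and do not appear in the positional annotation).
    """

    id: str
    type: str  # "gene" | "transcript"
    chrom: str
    strand: str
    start: int
    end: int
    role: str | None = None
    exons: list[tuple[int, int]] = field(default_factory=list)
    parent_id: str | None = None
    biotype: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise AnnotationError(
                f"feature {self.id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"feature {self.id}: bad strand {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = None
        for (s, e) in self.exons:
            if s < self.start or e > self.end or e <= s:
                raise AnnotationError(
                    f"feature {self.id}: exon [{s}, {e}) outside span "
                    f"[{self.start}, {self.end})"
                )
            if prev_end is not None and s < prev_end:
                raise AnnotationError(f"feature {self.id}: overlapping exons")
            prev_end = e

    @property
    def length(self) -> int:
        """Spliced length if exons are present, else span length."""
        if self.exons:
            return sum(e - s for s, e in self.exons)
        return self.end - self.start

    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out


@dataclass
class GenomeAnnotation:
    """A collection of gene/transcript models with unique ids."""

    features: list[FeatureModel]

    def __post_init__(self) -> None:
        self._by_id: dict[str, FeatureModel] = {}
        self._children: dict[str, list[FeatureModel]] = {}
        for f in self.features:
            if f.id in self._by_id:
                raise AnnotationError(f"duplicate feature id {f.id!r}")
            self._by_id[f.id] = f
        for f in self.features:
            if f.parent_id:
                self._children.setdefault(f.parent_id, []).append(f)

    def children(self, fid: str) -> list[FeatureModel]:
        return self._children.get(fid, [])

    def model_exons(self, fid: str) -> list[tuple[int, int]]:
        """Exon intervals of a feature, rolled up from child transcripts
        when the feature itself carries none; falls back to the full span."""
        f = self._by_id[fid]
        if f.exons:
            return f.exons
        exons = sorted(
            {e for child in self.children(fid) for e in child.exons}
        )
        return exons if exons else [(f.start, f.end)]

    def model_introns(self, fid: str) -> list[tuple[int, int]]:
        exons = self.model_exons(fid)
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(exons, exons[1:]) if s2 > e1
        ]

    def __getitem__(self, fid: str) -> FeatureModel:
        return self._by_id[fid]

    def __contains__(self, fid: str) -> bool:
        return fid in self._by_id

    def __len__(self) -> int:
        return len(self.features)

    def get(self, fid: str) -> FeatureModel | None:
        return self._by_id.get(fid)

    def genes(self, roles: Iterable[str] | None = None) -> list[FeatureModel]:
        roles = set(roles) if roles is not None else None
        return [
            f
            for f in self.features
            if f.type == "gene" and (roles is None or f.role in roles)
        ]

    def transcripts(self, roles: Iterable[str] | None = None) -> list[FeatureModel]:
        roles = set(roles) if roles is not None else None
        return [
            f
            for f in self.features
            if f.type == "transcript" and (roles is None or f.role in roles)
        ]

    def feature_lengths(self) -> dict[str, int]:
        return {f.id: f.length for f in self.features}


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _prescan_gff3(path: Path) -> None:
    """Cheap structural validation with line numbers before real parsing."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise AnnotationError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if end < start:
                raise AnnotationError(
                    f"{path}: line {lineno}: end < start ({end} < {start})"
                )


def read_gff3(path: str | Path) -> GenomeAnnotation:
    """Parse a GFF3 file into a :class:`GenomeAnnotation`.

    1-based inclusive file coordinates are converted to 0-based half-open
    here and nowhere else.  ``role`` and ``biotype`` attributes are captured;
    unknown feature types are ignored with a warning.
    """
    path = Path(path)
    _prescan_gff3(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )

    features: list[FeatureModel] = []
    skipped: set[str] = set()
    exons_by_parent: dict[str, list[tuple[int, int]]] = {}
    for f in db.all_features(order_by=("seqid", "start", "file_order")):
        if f.featuretype in _EXON_TYPES:
            for parent in f.attributes.get("Parent", []):
                exons_by_parent.setdefault(parent, []).append((f.start - 1, f.end))
        elif f.featuretype not in (_GENE_TYPES | _TRANSCRIPT_TYPES):
            skipped.add(f.featuretype)

    for f in db.all_features(order_by=("seqid", "start", "file_order")):
        if f.featuretype in _EXON_TYPES or f.featuretype in skipped:
            continue
        ftype = "gene" if f.featuretype in _GENE_TYPES else "transcript"
        role = (f.attributes.get("role") or [None])[0]
        biotype = (f.attributes.get("biotype") or [None])[0]
        if role is None and f.featuretype in ("lnc_RNA", "lncRNA"):
            role = "lncRNA"
        parent = (f.attributes.get("Parent") or [None])[0]
        features.append(
            FeatureModel(
                id=f.id,
                type=ftype,
                chrom=f.seqid,
                strand=f.strand if f.strand in "+-" else "+",
                start=f.start - 1,
                end=f.end,
                role=role,
                exons=exons_by_parent.get(f.id, []),
                parent_id=parent,
                biotype=biotype,
            )
        )
    if skipped:
        log.warning("read_gff3: ignored feature types %s", sorted(skipped))
    return GenomeAnnotation(features)


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write the annotation back to GFF3 (1-based inclusive at the boundary).

    Reading the result with :func:`read_gff3` reproduces the coordinates
    exactly.
    """
    path = Path(path)
    lines = ["##gff-version 3"]
    order = sorted(annotation.features, key=lambda f: (f.chrom, f.start, f.id))
    for f in order:
        attrs = [f"ID={f.id}"]
        if f.parent_id:
            attrs.append(f"Parent={f.parent_id}")
        if f.role:
            attrs.append(f"role={f.role}")
        if f.biotype:
            attrs.append(f"biotype={f.biotype}")
        if f.type == "gene":
            ftype = "gene"
        else:
            ftype = "lnc_RNA" if f.role == "lncRNA" else "mRNA"
        lines.append(
            "\t".join(
                [
                    f.chrom,
                    "lmrnet",
                    ftype,
                    str(f.start + 1),
                    str(f.end),
                    ".",
                    f.strand,
                    ".",
                    ";".join(attrs),
                ]
            )
        )
        for (s, e) in f.exons:
            lines.append(
                "\t".join(
                    [
                        f.chrom,
                        "lmrnet",
                        "exon",
                        str(s + 1),
                        str(e),
                        ".",
                        f.strand,
                        ".",
                        f"Parent={f.id}",
                    ]
                )
            )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


class ExpressionError(ValueError):
    """Raised for malformed expression tables / sample sheets."""


@dataclass
class ExpressionMatrix:
    """Features x samples abundance table with role and condition labels.

    ``data`` is a dense non-negative DataFrame (features as rows).  Every
    sample must have a condition label; roles may cover a subset of features
    only when the matrix mixes molecule classes is disallowed -- all features
    carry a role.
    """

    data: pd.DataFrame
    roles: dict[str, str]
    conditions: dict[str, str]
    unit: str = "raw_count"

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ExpressionError(f"unknown unit {self.unit!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ExpressionError(f"duplicated feature id(s): {dups[:5]}")
        if (self.data.values < 0).any():
            raise ExpressionError("negative values in expression matrix")
        missing_cond = [s for s in self.data.columns if s not in self.conditions]
        if missing_cond:
            raise ExpressionError(f"samples without condition: {missing_cond}")
        missing_role = [f for f in self.data.index if f not in self.roles]
        if missing_role:
            raise ExpressionError(
                f"features without role label: {missing_role[:5]} "
                f"({len(missing_role)} total)"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def condition_order(self) -> list[str]:
        """Distinct conditions in sample-sheet column order."""
        seen: list[str] = []
        for s in self.sample_ids:
            c = self.conditions[s]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids if self.conditions[s] == condition]

    def subset_roles(self, roles: Iterable[str]) -> "ExpressionMatrix":
        roles = set(roles)
        keep = [f for f in self.feature_ids if self.roles[f] in roles]
        return self.subset_features(keep)

    def subset_features(self, ids: Iterable[str]) -> "ExpressionMatrix":
        keep = [f for f in ids if f in set(self.feature_ids)]
        return ExpressionMatrix(
            data=self.data.loc[keep],
            roles={f: self.roles[f] for f in keep},
            conditions=dict(self.conditions),
            unit=self.unit,
        )

    def with_values(self, values: pd.DataFrame, unit: str) -> "ExpressionMatrix":
        return ExpressionMatrix(
            data=values,
            roles=dict(self.roles),
            conditions=dict(self.conditions),
            unit=unit,
        )


def read_sample_sheet(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "condition"} <= set(df.columns):
        raise ExpressionError(f"{path}: sample sheet needs columns sample, condition")
    if df["sample"].duplicated().any():
        raise ExpressionError(f"{path}: duplicated sample ids")
    if df["condition"].isna().any():
        raise ExpressionError(f"{path}: sample missing condition")
    return dict(zip(df["sample"], df["condition"]))


def read_roles(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"feature_id", "role"} <= set(df.columns):
        raise ExpressionError(f"{path}: roles table needs columns feature_id, role")
    bad = sorted(set(df["role"]) - set(ROLES))
    if bad:
        raise ExpressionError(f"{path}: unknown roles {bad}")
    return dict(zip(df["feature_id"], df["role"]))


def read_counts(
    counts_path: str | Path,
    sample_sheet: str | Path | Mapping[str, str],
    roles: str | Path | Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read an integer count table (feature_id x samples, TSV).

    ``sample_sheet`` and ``roles`` may be paths or already-parsed mappings.
    Duplicated feature ids, negative values and samples absent from the
    sheet are rejected.
    """
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise ExpressionError(f"{counts_path}: duplicated feature id(s): {dups[:5]}")
    if not all(pd.api.types.is_numeric_dtype(t) for t in df.dtypes):
        raise ExpressionError(f"{counts_path}: non-numeric values")
    if (df.values < 0).any():
        raise ExpressionError(f"{counts_path}: negative count")
    conditions = (
        dict(sample_sheet)
        if isinstance(sample_sheet, Mapping)
        else read_sample_sheet(sample_sheet)
    )
    missing = [s for s in df.columns if s not in conditions]
    if missing:
        raise ExpressionError(
            f"{counts_path}: columns not in sample sheet: {missing}"
        )
    if roles is None:
        role_map = {f: "mRNA" for f in df.index}
    elif isinstance(roles, Mapping):
        role_map = {f: roles[f] for f in df.index if f in roles}
    else:
        parsed = read_roles(roles)
        role_map = {f: parsed[f] for f in df.index if f in parsed}
    return ExpressionMatrix(
        data=df,
        roles=role_map,
        conditions={s: conditions[s] for s in df.columns},
        unit="raw_count",
    )


def write_counts(matrix: ExpressionMatrix, counts_path: str | Path) -> None:
    df = matrix.data
    if matrix.unit == "raw_count":
        df = df.astype(int)
    df.to_csv(counts_path, sep="\t", index_label="feature_id")


def write_sample_sheet(conditions: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample": list(conditions), "condition": [conditions[s] for s in conditions]}
    ).to_csv(path, sep="\t", index=False)


def write_roles(roles: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"feature_id": list(roles), "role": [roles[f] for f in roles]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FastaRecord:
    seq: str
    was_rna: bool


def read_fasta(path: str | Path, with_flags: bool = False):
    """Read a FASTA file into ``{id: sequence}``.

    Sequences are uppercased and U is normalized to T; with
    ``with_flags=True`` each value is a :class:`FastaRecord` whose
    ``was_rna`` flag records that a U was seen.  Duplicate ids are an error;
    an empty file yields an empty map.
    """
    out: dict[str, FastaRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        raw = str(rec.seq).upper()
        was_rna = "U" in raw
        out[rec.id] = FastaRecord(seq=raw.replace("U", "T"), was_rna=was_rna)
    if with_flags:
        return out
    return {k: v.seq for k, v in out.items()}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
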