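"""Custom transposable-element annotation building.

Repeat instances (RepeatMasker-style intervals with a repeat name and family
label) are merged with a canonical gene/exon annotation: any repeat sharing
at least one base with a gene-associated exon, on either strand, is discarded
as a potential false positive; the survivors are grouped into repeat families
and into a single all-member meta-gene, and written out as a custom GTF next
to the canonical gene lines.

Coordinates are GTF convention throughout: 1-based, inclusive on both ends.
Two intervals overlap iff ``a.start <= b.end and b.start <= a.end``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "TEInstance",
    "TEFamily",
    "GtfParseError",
    "read_gtf",
    "write_gtf",
    "write_custom_gtf",
    "read_repeat_table",
    "write_repeat_table",
    "read_family_map",
    "filter_exon_overlaps",
    "group_families",
    "build_annotation",
    "intervals_overlap",
]

META_GENE = "TE_metagene"


class GtfParseError(ValueError):
    """Malformed GTF input; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass
class GenomicInterval:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    feature_type: str = "exon"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def intervals_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """>= 1 shared base under 1-based inclusive coordinates; strand-agnostic."""
    return a.chrom == b.chrom and a.start <= b.end and b.start <= a.end


@dataclass
class TEInstance:
    """One repeat instance with its family label."""

    interval: GenomicInterval
    repeat_name: str
    family: str
    instance_id: str

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("family label must be non-empty")


@dataclass
class TEFamily:
    """A named group of repeat instances (by instance_id)."""

    name: str
    member_ids: list[str]

    @property
    def size(self) -> int:
        return len(self.member_ids)


# ---------------------------------------------------------------------------
# GTF I/O (1-based inclusive, attributes kept in input order)

def _parse_attributes(text: str, line_number: int) -> dict:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            raise GtfParseError(f"malformed attribute {chunk!r}", line_number)
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path) -> list[GenomicInterval]:
    """Parse a GTF file into intervals; attribute key/values preserved."""
    records: list[GenomicInterval] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"expected 9 tab-separated fields, got {len(fields)}", i)
            chrom, source, feature, start, end, score, strand, frame, attr = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise GtfParseError(f"non-integer coordinates {start!r}..{end!r}", i) from None
            if end_i < start_i:
                raise GtfParseError(f"end {end_i} < start {start_i}", i)
            if strand not in {"+", "-", "."}:
                raise GtfParseError(f"bad strand {strand!r}", i)
            attrs = _parse_attributes(attr, i)
            attrs["_source"] = source
            records.append(
                GenomicInterval(
                    chrom=chrom,
                    start=start_i,
                    end=end_i,
                    strand=strand,
                    feature_type=feature,
                    attributes=attrs,
                )
            )
    return records


def _format_record(rec: GenomicInterval) -> str:
    attrs = {k: v for k, v in rec.attributes.items() if not k.startswith("_")}
    source = rec.attributes.get("_source", "retinomimic")
    attr_text = " ".join(f'{k} "{v}";' for k, v in attrs.items())
    return "\t".join(
        [
            rec.chrom,
            source,
            rec.feature_type,
            str(rec.start),
            str(rec.end),
            ".",
            rec.strand,
            ".",
            attr_text,
        ]
    )


def write_gtf(records: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(_format_record(rec) + "\n")


def _repeat_record(te: TEInstance) -> GenomicInterval:
    iv = te.interval
    attrs = dict(iv.attributes)
    attrs.update(
        {
            "gene_id": te.instance_id,
            "instance_id": te.instance_id,
            "repeat_name": te.repeat_name,
            "family": te.family,
        }
    )
    return GenomicInterval(iv.chrom, iv.start, iv.end, iv.strand, "repeat", attrs)


def write_custom_gtf(
    genes: Sequence[GenomicInterval],
    exons: Sequence[GenomicInterval],
    retained_repeats: Sequence[TEInstance],
    path,
) -> None:
    """Canonical gene/exon lines followed by repeat lines.

    Repeat lines carry family and instance_id attributes. Output ordering is
    fixed (genes, exons, repeats — each by chrom, start, id) so the file is
    byte-stable and round-trips through :func:`read_gtf`.
    """

    def _key(rec: GenomicInterval):
        return (rec.chrom, rec.start, rec.end, rec.attributes.get("gene_id", ""))

    ordered = sorted(genes, key=_key) + sorted(exons, key=_key)
    ordered += [
        _repeat_record(te)
        for te in sorted(retained_repeats, key=lambda t: (t.interval.chrom, t.interval.start, t.instance_id))
    ]
    write_gtf(ordered, path)


# ---------------------------------------------------------------------------
# Repeat table (RepeatMasker-style TSV) I/O

_REPEAT_COLUMNS = ("chrom", "start", "end", "strand", "repeat_name", "family")


def read_repeat_table(path) -> list[TEInstance]:
    """Read a tab-delimited repeat table: chrom, start, end, strand, repeat_name, family."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    missing = set(_REPEAT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"repeat table missing columns: {sorted(missing)}")
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        iid = getattr(row, "instance_id", None) or f"{row.repeat_name}_{i}"
        out.append(
            TEInstance(
                GenomicInterval(str(row.chrom), int(row.start), int(row.end), str(row.strand), "repeat"),
                repeat_name=str(row.repeat_name),
                family=str(row.family),
                instance_id=str(iid),
            )
        )
    ids = [t.instance_id for t in out]
    if len(set(ids)) != len(ids):
        raise ValueError("instance_id values must be unique")
    return out


def write_repeat_table(repeats: Sequence[TEInstance], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "chrom": t.interval.chrom,
                "start": t.interval.start,
                "end": t.interval.end,
                "strand": t.interval.strand,
                "repeat_name": t.repeat_name,
                "family": t.family,
                "instance_id": t.instance_id,
            }
            for t in repeats
        ]
    ).to_csv(path, sep="\t", index=False)


def read_family_map(path) -> dict[str, str]:
    """Two-column TSV repeat_name -> family."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if not {"repeat_name", "family"} <= set(df.columns):
        raise ValueError("family map needs columns repeat_name, family")
    return dict(zip(df["repeat_name"].astype(str), df["family"].astype(str)))


# ---------------------------------------------------------------------------
# Core operations

def filter_exon_overlaps(
    repeats: Sequence[TEInstance],
    exons: Sequence[GenomicInterval],
    chrom_aliases: Mapping[str, str] | None = None,
) -> tuple[list[TEInstance], list[dict]]:
    """Discard every repeat sharing >= 1 bp with any gene-associated exon.

    Overlap is strand-agnostic ("any overlap"). Returns the retained
    instances and a discard log (one dict per discarded repeat naming the
    first offending exon).

    ``chrom_aliases`` optionally maps repeat-table chromosome names onto the
    exon annotation's names ("1" -> "chr1"); any repeat chromosome that is
    absent from the exon annotation after aliasing triggers a warning listing
    the unmatched names.
    """
    aliases = dict(chrom_aliases or {})
    trees: dict[str, IntervalTree] = {}
    for ex in exons:
        # half-open conversion for the interval index: [start, end + 1)
        trees.setdefault(ex.chrom, IntervalTree()).addi(ex.start, ex.end + 1, ex)

    retained: list[TEInstance] = []
    discard_log: list[dict] = []
    unmatched: set[str] = set()
    for te in repeats:
        chrom = aliases.get(te.interval.chrom, te.interval.chrom)
        tree = trees.get(chrom)
        if tree is None and exons:
            unmatched.add(te.interval.chrom)
        hits = tree.overlap(te.interval.start, te.interval.end + 1) if tree else ()
        if hits:
            hit = min(hits, key=lambda h: (h.begin, h.end))
            ex = hit.data
            discard_log.append(
                {
                    "instance_id": te.instance_id,
                    "repeat_name": te.repeat_name,
                    "family": te.family,
                    "chrom": te.interval.chrom,
                    "start": te.interval.start,
                    "end": te.interval.end,
                    "reason": f"overlaps exon {ex.chrom}:{ex.start}-{ex.end}",
                }
            )
        else:
            retained.append(te)
    if unmatched:
        warnings.warn(
            "repeat chromosomes absent from exon annotation: "
            + ", ".join(sorted(unmatched)),
            stacklevel=2,
        )
    return retained, discard_log


def group_families(
    repeats: Sequence[TEInstance],
    family_map: Mapping[str, str] | None = None,
    strict: bool = True,
) -> tuple[list[TEFamily], TEFamily]:
    """Partition repeat instances into families plus one all-member meta-gene.

    With a ``family_map`` (repeat_name -> family) the mapped label overrides
    the instance's own; an unmapped repeat_name raises under ``strict`` and is
    dropped otherwise. Families are returned sorted by name; the meta-gene is
    the union of every family's members.
    """
    members: dict[str, list[str]] = {}
    meta: list[str] = []
    for te in repeats:
        if family_map is not None:
            fam = family_map.get(te.repeat_name)
            if fam is None:
                if strict:
                    raise KeyError(f"repeat_name {te.repeat_name!r} not in family map")
                continue
        else:
            fam = te.family
        members.setdefault(fam, []).append(te.instance_id)
        meta.append(te.instance_id)
    families = [TEFamily(name, ids) for name, ids in sorted(members.items())]
    return families, TEFamily(META_GENE, meta)


def build_annotation(
    gtf_path,
    repeats_path,
    out_gtf_path,
    family_map_path=None,
    strict: bool = False,
    discard_log_path=None,
) -> dict:
    """End-to-end annotation build: parse, filter, group, write.

    Returns a summary dict (counts of input/retained/discarded repeats and
    family sizes).
    """
    import pandas as pd

    records = read_gtf(gtf_path)
    genes = [r for r in records if r.feature_type == "gene"]
    exons = [r for r in records if r.feature_type == "exon"]
    repeats = read_repeat_table(repeats_path)
    family_map = read_family_map(family_map_path) if family_map_path else None
    retained, discards = filter_exon_overlaps(repeats, exons)
    families, meta = group_families(retained, family_map, strict=strict)
    write_custom_gtf(genes, exons, retained, out_gtf_path)
    if discard_log_path is not None:
        pd.DataFrame(
            discards,
            columns=["instance_id", "repeat_name", "family", "chrom", "start", "end", "reason"],
        ).to_csv(discard_log_path, sep="\t", index=False)
    return {
        "n_input_repeats": len(repeats),
        "n_retained": len(retained),
        "n_discarded": len(discards),
        "n_families": len(families),
        "family_sizes": {f.name: f.size for f in families},
        "metagene_size": meta.size,
    }
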