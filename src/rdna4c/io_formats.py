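"""Readers and writers for the genomic text formats the pipeline consumes.

Conventions handled here, and only here:

* bedGraph and BED are 0-based half-open (kept as-is).
* GTF/GFF3 and wiggle are 1-based; GTF/GFF3 are closed intervals, converted
  to internal 0-based half-open as ``(start - 1, end)``.
* Writers emit deterministic ordering so identical inputs give identical
  bytes.

Validation is strict by design: overlapping bedGraph records, negative
values, duplicate gene ids and malformed lines raise rather than warn, and
parse errors name the offending line.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

from .core import (
    BedGraphRecord,
    ContactTrack,
    GeneRecord,
    GeneSet,
    GenomicInterval,
    ParseError,
    RepeatRecord,
    SignalTrack,
    StateAnnotation,
    StateSegment,
    ValidationError,
)

_REPEAT_CLASS_ALIASES = {
    "ltr": "LTR",
    "line": "LINE",
    "sine": "SINE",
    "low_complexity": "low_complexity",
    "simple_repeat": "low_complexity",
    "satellite": "low_complexity",
}


def _data_lines(path: str):
    """Yield ``(lineno, stripped_line)`` skipping comments/track/browser lines."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_bedgraph(path: str, sample_id: str = "", condition: str = "") -> ContactTrack:
    """Read a 4-column bedGraph into a validated :class:`ContactTrack`.

    Records must be non-overlapping within each chromosome; values must be
    non-negative. Raises :class:`ParseError` with the line number on
    malformed input and :class:`ValidationError` on invariant violations.
    """
    records: list[BedGraphRecord] = []
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) != 4:
            raise ParseError(
                f"expected 4 columns, got {len(fields)}", path=path, line=lineno
            )
        chrom, s, e, v = fields
        try:
            start, end, value = int(s), int(e), float(v)
        except ValueError as exc:
            raise ParseError(f"bad numeric field: {exc}", path=path, line=lineno)
        try:
            records.append(BedGraphRecord(GenomicInterval(chrom, start, end), value))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return ContactTrack(records, sample_id=sample_id, condition=condition)


def write_bedgraph(track: ContactTrack | SignalTrack, path: str) -> None:
    """Write a track as bedGraph; integer-valued records print without decimals."""
    with open(path, "w") as fh:
        name = getattr(track, "sample_id", "") or getattr(track, "name", "") or "track"
        fh.write(f'track type=bedGraph name="{name}"\n')
        for rec in track.records:
            v = rec.value
            vstr = str(int(v)) if float(v).is_integer() else repr(float(v))
            iv = rec.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{vstr}\n")


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')
_GFF3_ATTR = re.compile(r"(\w+)=([^;]*)")


def _parse_attrs(attr_field: str, dialect: str) -> dict[str, str]:
    pattern = _GTF_ATTR if dialect == "gtf" else _GFF3_ATTR
    return {k: v for k, v in pattern.findall(attr_field)}


def read_gene_annotation(path: str, dialect: str = "gtf") -> GeneSet:
    """Read gene models from GTF (Ensembl dialect) or GFF3 into a GeneSet.

    1-based closed coordinates become 0-based half-open. ``gene`` features
    define gene bodies; ``exon``/``five_prime_utr``/``three_prime_utr``
    features are grouped under their gene via the gene_id attribute.
    """
    if dialect not in ("gtf", "gff3"):
        raise ParseError(f"unknown annotation dialect {dialect!r}", path=path)
    genes: dict[str, dict] = {}
    order: list[str] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(
                f"expected 9 tab-separated columns, got {len(fields)}",
                path=path,
                line=lineno,
            )
        chrom, _src, feature, s, e, _score, strand, _frame, attrs = fields
        try:
            start1, end1 = int(s), int(e)
        except ValueError as exc:
            raise ParseError(f"bad coordinate: {exc}", path=path, line=lineno)
        if end1 < start1:
            raise ValidationError(f"{path}:{lineno}: end {end1} < start {start1}")
        attr_map = _parse_attrs(attrs, dialect)
        gene_id = attr_map.get("gene_id")
        if gene_id is None and dialect == "gff3":
            # GFF3 gene rows carry ID=...; children point at it via Parent=
            gene_id = attr_map.get("ID") if feature == "gene" else attr_map.get("Parent")
        if gene_id is None:
            raise ParseError("missing gene_id attribute", path=path, line=lineno)
        iv = GenomicInterval(chrom, start1 - 1, end1)
        kind = feature.lower()
        if kind == "gene":
            if gene_id in genes and genes[gene_id]["interval"] is not None:
                raise ValidationError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            entry = genes.setdefault(
                gene_id,
                {"interval": None, "strand": strand, "symbol": "", "exons": [],
                 "utr5": [], "utr3": []},
            )
            entry["interval"] = iv
            entry["strand"] = strand
            entry["symbol"] = attr_map.get("gene_name", attr_map.get("Name", gene_id))
            if gene_id not in order:
                order.append(gene_id)
        elif kind in ("exon", "five_prime_utr", "three_prime_utr", "5utr", "3utr"):
            entry = genes.setdefault(
                gene_id,
                {"interval": None, "strand": strand, "symbol": "", "exons": [],
                 "utr5": [], "utr3": []},
            )
            if gene_id not in order:
                order.append(gene_id)
            key = {"exon": "exons", "five_prime_utr": "utr5", "5utr": "utr5",
                   "three_prime_utr": "utr3", "3utr": "utr3"}[kind]
            entry[key].append(iv)
    out = []
    for gid in order:
        entry = genes[gid]
        body = entry["interval"]
        if body is None:
            # gene row absent: infer body as the span of its sub-features
            subs = entry["exons"] + entry["utr5"] + entry["utr3"]
            body = GenomicInterval(
                subs[0].chrom, min(s.start for s in subs), max(s.end for s in subs)
            )
        out.append(
            GeneRecord(
                gene_id=gid,
                symbol=entry["symbol"] or gid,
                interval=body,
                strand=entry["strand"],
                exons=tuple(sorted(entry["exons"], key=lambda i: i.start)),
                utr5=tuple(sorted(entry["utr5"], key=lambda i: i.start)),
                utr3=tuple(sorted(entry["utr3"], key=lambda i: i.start)),
            )
        )
    return GeneSet(out)


def write_gene_annotation(genes: GeneSet, path: str) -> None:
    """Write a GeneSet as Ensembl-style GTF (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start)):
            iv = g.interval
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.symbol}";'
            fh.write(
                f"{iv.chrom}\trdna4c\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{ex.chrom}\trdna4c\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


def read_bed(path: str) -> list[tuple[GenomicInterval, str, float]]:
    """Read BED3-6 as ``(interval, name, score)`` tuples (0-based half-open)."""
    out = []
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 3:
            raise ParseError(
                f"expected >= 3 columns, got {len(fields)}", path=path, line=lineno
            )
        try:
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
        except ValueError as exc:
            raise ParseError(f"bad coordinate: {exc}", path=path, line=lineno)
        name = fields[3] if len(fields) > 3 else ""
        score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
        out.append((iv, name, score))
    return out


def read_repeats_bed(path: str) -> list[RepeatRecord]:
    """Read a Dfam-style repeat BED; column 4 is ``family[/class]``."""
    repeats = []
    for iv, name, _score in read_bed(path):
        family, _, cls = name.partition("/")
        repeat_class = _REPEAT_CLASS_ALIASES.get(cls.lower(), "other") if cls else "other"
        repeats.append(RepeatRecord(iv, family=family, repeat_class=repeat_class))
    return repeats


def write_repeats_bed(repeats: Sequence[RepeatRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in sorted(repeats, key=lambda r: (r.interval.chrom, r.interval.start)):
            iv = r.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.family}/{r.repeat_class}\n")


def read_state_gff(path: str) -> StateAnnotation:
    """Read a 9-state chromatin segmentation from GFF3 (1-based closed)."""
    segs = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(
                f"expected 9 columns, got {len(fields)}", path=path, line=lineno
            )
        chrom, _src, _feat, s, e, _score, _strand, _frame, attrs = fields
        m = re.search(r"state=(\d+)", attrs)
        if m is None:
            raise ParseError("missing state=N attribute", path=path, line=lineno)
        try:
            iv = GenomicInterval(chrom, int(s) - 1, int(e))
        except ValueError as exc:
            raise ParseError(f"bad coordinate: {exc}", path=path, line=lineno)
        segs.append(StateSegment(iv, int(m.group(1))))
    return StateAnnotation(segs)


def write_state_gff(states: StateAnnotation, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seg in states.segments():
            iv = seg.interval
            fh.write(
                f"{iv.chrom}\trdna4c\tchromatin_state\t{iv.start + 1}\t{iv.end}\t.\t"
                f".\t.\tstate={seg.state}\n"
            )


def read_wiggle(path: str) -> SignalTrack:
    """Read fixedStep/variableStep wiggle into a SignalTrack.

    Wiggle positions are 1-based; each value covers ``span`` bases starting
    at its position, converted to 0-based half-open records.
    """
    records: list[BedGraphRecord] = []
    mode = None  # ("fixed", chrom, next_start0, step, span) or ("variable", chrom, span)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(f.split("=") for f in line.split()[1:])
                if "chrom" not in kv or "start" not in kv:
                    raise ParseError("fixedStep needs chrom= and start=", path, lineno)
                step = int(kv.get("step", 1))
                span = int(kv.get("span", step))
                mode = ["fixed", kv["chrom"], int(kv["start"]) - 1, step, span]
            elif line.startswith("variableStep"):
                kv = dict(f.split("=") for f in line.split()[1:])
                if "chrom" not in kv:
                    raise ParseError("variableStep needs chrom=", path, lineno)
                mode = ["variable", kv["chrom"], int(kv.get("span", 1))]
            elif mode is None:
                raise ParseError("data before any step declaration", path, lineno)
            elif mode[0] == "fixed":
                _, chrom, pos, step, span = mode
                try:
                    value = float(line)
                except ValueError as exc:
                    raise ParseError(f"bad value: {exc}", path, lineno)
                records.append(
                    BedGraphRecord(GenomicInterval(chrom, pos, pos + span), value)
                )
                mode[2] = pos + step
            else:
                _, chrom, span = mode
                fields = line.split()
                if len(fields) != 2:
                    raise ParseError("variableStep lines are 'pos value'", path, lineno)
                try:
                    pos0, value = int(fields[0]) - 1, float(fields[1])
                except ValueError as exc:
                    raise ParseError(f"bad field: {exc}", path, lineno)
                records.append(
                    BedGraphRecord(GenomicInterval(chrom, pos0, pos0 + span), value)
                )
    return SignalTrack(records)


def write_wiggle_fixedstep(track: SignalTrack, path: str) -> None:
    """Write a SignalTrack whose records are uniform tiles as fixedStep wiggle."""
    with open(path, "w") as fh:
        by_chrom = track.by_chrom()
        for chrom in sorted(by_chrom):
            starts, ends, values = by_chrom[chrom]
            i = 0
            n = len(starts)
            while i < n:
                span = int(ends[i] - starts[i])
                j = i
                while (
                    j + 1 < n
                    and ends[j + 1] - starts[j + 1] == span
                    and starts[j + 1] == starts[j] + span
                ):
                    j += 1
                fh.write(
                    f"fixedStep chrom={chrom} start={int(starts[i]) + 1} "
                    f"step={span} span={span}\n"
                )
                for v in values[i : j + 1]:
                    fh.write(f"{v:g}\n")
                i = j + 1
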