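"""Batch orchestration: per-sample directory layout, stage ordering, logging.

A sample travels through six stages: read trimming and assembly (external
tools, invoked only in reads mode), candidate discovery and selection,
ambiguous-base correction, structure resolution, canonical standardization,
annotation transfer, and emission of GenBank + feature-table files.  Samples
are independent: one failure never stops the batch.  Every stage appends to
its own log file whose last line states success or the error.

Pre-assembled mode (an assembly FASTA instead of reads) is first-class: the
core algorithms run with no external binaries.
"""

from __future__ import annotations

import os
import re
import subprocess
import traceback
from dataclasses import dataclass, field

from . import annotate as _annotate
from . import formats, standardize, structure
from .align import locate
from .errors import (
    AmbiguousStructure,
    CandidateOverflow,
    ConfigError,
    NoQuadripartite,
    PlastopipeError,
)
from .model import (
    AnnotationSet,
    CircularSequence,
    SequenceRecord,
    StandardizedAssembly,
    reverse_complement,
)

#: subsample handed to the read trimmer, and the assembler's defaults
TRIMMER_SUBSAMPLE_READS = 10_000_000

DEFAULT_THRESHOLDS = {
    "structure": {"min_length": 1000, "min_identity": 0.99},
    "correction": {"k": 21, "min_depth": 5, "min_majority": 0.7},
    "annotate": {"rounds": _annotate.DEFAULT_ROUNDS},
}


@dataclass
class SampleConfig:
    """Everything one sample needs to run."""

    prefix: str
    reference_genbank: str
    reads_forward: str | None = None
    reads_reverse: str | None = None
    assembly: str | None = None
    seed: str | None = None
    size_range: tuple[int, int] = (120_000, 200_000)
    subsample_reads: int = TRIMMER_SUBSAMPLE_READS
    thresholds: dict = field(default_factory=lambda: {})
    tool_paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[\w.-]+", self.prefix):
            raise ConfigError(f"prefix {self.prefix!r} is not a valid directory name")
        if self.size_range[0] >= self.size_range[1]:
            raise ConfigError(f"invalid size range {self.size_range}")
        has_reads = bool(self.reads_forward and self.reads_reverse)
        if not has_reads and not self.assembly:
            raise ConfigError(
                f"sample {self.prefix!r}: needs either a read pair or an assembly"
            )

    def threshold(self, section: str) -> dict:
        merged = dict(DEFAULT_THRESHOLDS[section])
        merged.update(self.thresholds.get(section, {}))
        return merged


def parse_range(text: str) -> tuple[int, int]:
    """Parse an assembly size range like '120000-200000'."""
    m = re.fullmatch(r"\s*(\d+)\s*-\s*(\d+)\s*", text)
    if not m:
        raise ConfigError(f"malformed size range {text!r} (expected MIN-MAX)")
    lo, hi = int(m.group(1)), int(m.group(2))
    if lo >= hi:
        raise ConfigError(f"size range {text!r}: minimum must be below maximum")
    return lo, hi


def parse_batch_file(path: str, **defaults) -> list[SampleConfig]:
    """Parse the file-of-files batch manifest.

    One sample per line, whitespace-separated: ``prefix forward.fq reverse.fq``
    in reads mode or ``prefix assembly.fasta`` in pre-assembled mode.  Blank
    lines and ``#`` comments are ignored.  Remaining SampleConfig fields come
    from ``defaults``.
    """
    samples: list[SampleConfig] = []
    seen: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) == 3:
                prefix, fwd, rev = fields
                kwargs = {"reads_forward": fwd, "reads_reverse": rev}
                paths = [fwd, rev]
            elif len(fields) == 2:
                prefix, asm = fields
                kwargs = {"assembly": asm}
                paths = [asm]
            else:
                raise ConfigError(
                    f"{path}:{lineno}: expected 'prefix fwd rev' or 'prefix assembly', "
                    f"got {len(fields)} fields"
                )
            if prefix in seen:
                raise ConfigError(
                    f"{path}:{lineno}: duplicate prefix {prefix!r} "
                    f"(first used on line {seen[prefix]})"
                )
            seen[prefix] = lineno
            for p in paths:
                if not os.path.exists(p):
                    raise ConfigError(f"{path}:{lineno}: input file {p!r} does not exist")
            samples.append(SampleConfig(prefix=prefix, **kwargs, **defaults))
    if not samples:
        raise ConfigError(f"{path}: no samples in batch file")
    return samples


# ---------------------------------------------------------------------------
# External tool adapters (reads mode only)


def run_trimmer(sample: SampleConfig, outdir: str, log_path: str) -> tuple[str, str]:
    """Adapter around the external read trimmer (fastp-compatible CLI)."""
    tool = sample.tool_paths.get("trimmer", "fastp")
    out1 = os.path.join(outdir, f"{sample.prefix}.trimmed.R1.fastq")
    out2 = os.path.join(outdir, f"{sample.prefix}.trimmed.R2.fastq")
    cmd = [
        tool,
        "-i", sample.reads_forward, "-I", sample.reads_reverse,
        "-o", out1, "-O", out2,
        "--reads_to_process", str(sample.subsample_reads),
        "-j", os.path.join(outdir, "fastp.json"), "-h", "/dev/null",
    ]
    with open(log_path, "a") as log:
        subprocess.run(cmd, check=True, stdout=log, stderr=log)
    return out1, out2


def run_assembler(sample: SampleConfig, config_path: str, outdir: str, log_path: str) -> None:
    """Adapter around the external organelle assembler (NOVOPlasty-style)."""
    tool = sample.tool_paths.get("assembler")
    if not tool:
        raise ConfigError(f"sample {sample.prefix}: no assembler path configured")
    cmd = ["perl", tool, "-c", config_path] if tool.endswith(".pl") else [tool, "-c", config_path]
    with open(log_path, "a") as log:
        subprocess.run(cmd, check=True, cwd=outdir, stdout=log, stderr=log)


# ---------------------------------------------------------------------------
# Fallback orientation for IR-less molecules


def orient_whole_molecule(
    seq: CircularSequence, reference: SequenceRecord
) -> tuple[SequenceRecord, int, bool]:
    """Best-identity rotation/strand of the whole molecule against a reference.

    Used when no inverted repeat is found (some plastomes have lost one IR
    copy).  The start of the reference is located on both strands of the
    doubled target; the molecule is rotated to that position, on the strand
    with the better anchor hit.
    """
    probe = reference.bases[: min(300, len(reference.bases))]
    doubled = seq.bases + seq.bases
    max_edits = max(10, len(probe) // 4)
    fwd = locate(probe, doubled, max_edits)
    rev = locate(probe, reverse_complement(doubled), max_edits)
    best_fwd = max(fwd, key=lambda h: h[2], default=None)
    best_rev = max(rev, key=lambda h: h[2], default=None)
    L = len(seq)
    if best_rev is not None and (best_fwd is None or best_rev[2] > best_fwd[2]):
        bases = reverse_complement(seq.bases)
        hit = max(locate(probe, bases + bases, max_edits), key=lambda h: h[2])
        offset = hit[0] % L
        return SequenceRecord(seq.id, "oriented (no IR found)", bases[offset:] + bases[:offset]), offset, True
    if best_fwd is None:
        raise NoQuadripartite(
            f"{seq.id}: no inverted repeat and the reference anchor does not align"
        )
    offset = best_fwd[0] % L
    return (
        SequenceRecord(seq.id, "oriented (no IR found)", seq.bases[offset:] + seq.bases[:offset]),
        offset,
        False,
    )


# ---------------------------------------------------------------------------
# Per-sample run


@dataclass
class SampleResult:
    prefix: str
    status: str = "failed"
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    error: str = ""


@dataclass
class RunManifest:
    results: list[SampleResult] = field(default_factory=list)

    @property
    def n_complete(self) -> int:
        return sum(1 for r in self.results if r.status == "complete")

    def report(self) -> str:
        lines = ["#prefix\tstatus\tstages\twarnings\terror"]
        for r in self.results:
            stages = ",".join(f"{k}={v}" for k, v in r.stages.items())
            warns = ";".join(r.warnings) or "-"
            lines.append(f"{r.prefix}\t{r.status}\t{stages}\t{warns}\t{r.error or '-'}")
        return "\n".join(lines) + "\n"


class _StageLog:
    """Per-stage log file whose last line states success or the error."""

    def __init__(self, log_dir: str, stage: str):
        self.path = os.path.join(log_dir, f"{stage}.log")
        self.stage = stage

    def write(self, message: str) -> None:
        with open(self.path, "a") as fh:
            fh.write(message.rstrip("\n") + "\n")

    def success(self, message: str = "") -> None:
        self.write(f"SUCCESS: {self.stage} {message}".rstrip())

    def failure(self, message: str) -> None:
        self.write(f"ERROR: {message}")


def run_sample(sample: SampleConfig, outdir: str = ".") -> SampleResult:
    """Run one sample end to end, writing the prefix directory tree."""
    result = SampleResult(prefix=sample.prefix)
    base = os.path.join(outdir, sample.prefix)
    dirs = {name: os.path.join(base, name) for name in ("logs", "assembly", "standardized", "annotation")}
    for d in dirs.values():
        os.makedirs(d, exist_ok=True)

    def stage(name: str) -> _StageLog:
        return _StageLog(dirs["logs"], name)

    try:
        reference = formats.read_genbank(sample.reference_genbank)
        reads_paths: tuple[str, str] | None = None

        if sample.assembly:
            log = stage("assembly")
            log.write(f"pre-assembled mode: {sample.assembly}")
            records = formats.read_fasta(sample.assembly)
            if len(records) > 2:
                raise CandidateOverflow(
                    f"{sample.assembly}: {len(records)} candidate assemblies (at most 2 supported)"
                )
            candidates = [CircularSequence(r.id, r.bases) for r in records]
            if sample.reads_forward and sample.reads_reverse:
                reads_paths = (sample.reads_forward, sample.reads_reverse)
            log.success(f"{len(candidates)} candidate(s)")
            result.stages["assembly"] = "ok"
        else:
            log = stage("trim")
            reads_paths = run_trimmer(sample, dirs["assembly"], log.path)
            log.success()
            result.stages["trim"] = "ok"
            log = stage("assembly")
            config_path = os.path.join(dirs["assembly"], f"{sample.prefix}.assembler.config")
            formats.write_assembler_config(sample, reads_paths, config_path)
            run_assembler(sample, config_path, dirs["assembly"], log.path)
            records = formats.discover_assembler_output(dirs["assembly"], sample.prefix)
            candidates = [CircularSequence(r.id, r.bases) for r in records]
            log.success(f"{len(candidates)} candidate(s)")
            result.stages["assembly"] = "ok"

        st_kw = sample.threshold("structure")
        log = stage("select")
        chosen = standardize.select_candidate(candidates, reference, **st_kw)
        result.stages["select"] = "ok"
        log.success(f"selected candidate of length {len(chosen)}")

        log = stage("correct")
        corrected_entries = []
        if reads_paths is not None:
            corr_kw = sample.threshold("correction")
            pairs = list(formats.read_fastq_pairs(*reads_paths))
            rec = SequenceRecord(chosen.id, "", chosen.bases)
            rec, corrected_entries = standardize.correct_ambiguous(rec, pairs, **corr_kw)
            chosen = CircularSequence(rec.id, rec.bases)
            report_path = os.path.join(dirs["standardized"], f"{sample.prefix}.correction.tsv")
            with open(report_path, "w") as fh:
                fh.write(standardize.correction_report(corrected_entries))
            result.outputs["correction_report"] = report_path
            log.success(f"{sum(1 for e in corrected_entries if e.action == 'corrected')} corrected")
        else:
            log.success("skipped (no reads)")
        result.stages["correct"] = "ok"

        log = stage("standardize")
        try:
            repeats = structure.find_inverted_repeats(chosen, **st_kw)
            resolved = structure.resolve_quadripartite(chosen, repeats, reference=reference, **st_kw)
            std = standardize.canonicalize(chosen, resolved, reference, **st_kw)
            struct_path = os.path.join(dirs["standardized"], f"{sample.prefix}.structure.tsv")
            with open(struct_path, "w") as fh:
                fh.write(structure.structure_report(std.structure))
            result.outputs["structure_report"] = struct_path
            provenance = (
                f"candidate={std.candidate_index} rotation={std.rotation_offset} "
                f"flip={std.flipped} ssc_flip={std.ssc_flipped}"
            )
            standardized = std.sequence
        except (NoQuadripartite, AmbiguousStructure) as exc:
            msg = f"no quadripartite structure ({exc}); whole-molecule orientation fallback"
            result.warnings.append(msg)
            log.write(f"WARNING: {msg}")
            standardized, offset, flipped = orient_whole_molecule(chosen, reference.sequence)
            provenance = f"fallback rotation={offset} flip={flipped}"
        fasta_path = os.path.join(dirs["standardized"], f"{sample.prefix}.standardized.fasta")
        formats.write_fasta([standardized], fasta_path)
        result.outputs["standardized_fasta"] = fasta_path
        if not sample.size_range[0] <= len(standardized) <= sample.size_range[1]:
            msg = (
                f"assembly length {len(standardized)} outside expected range "
                f"{sample.size_range[0]}-{sample.size_range[1]}"
            )
            result.warnings.append(msg)
            log.write(f"WARNING: {msg}")
        log.success(provenance)
        result.stages["standardize"] = "ok"

        log = stage("annotate")
        ann_kw = sample.threshold("annotate")
        templates = _annotate.extract_reference_features(reference)
        mapped, unmapped = _annotate.map_features(standardized, templates, ann_kw["rounds"])
        annotation = _annotate.build_annotation(standardized, mapped, unmapped)
        annotation.organism = reference.organism
        _annotate.qc_internal_stops(annotation)
        report_path = os.path.join(dirs["annotation"], f"{sample.prefix}.annotation_report.tsv")
        with open(report_path, "w") as fh:
            fh.write(_annotate.annotation_report(annotation, mapped))
        result.outputs["annotation_report"] = report_path
        log.success(f"{len(mapped)} mapped, {len(unmapped)} unmapped, {len(annotation.qc_flags)} QC flags")
        result.stages["annotate"] = "ok"

        log = stage("export")
        gb_path = os.path.join(dirs["annotation"], f"{sample.prefix}.gb")
        tbl_path = os.path.join(dirs["annotation"], f"{sample.prefix}.tbl")
        formats.write_genbank(annotation, gb_path)
        formats.write_feature_table(annotation, tbl_path)
        result.outputs["genbank"] = gb_path
        result.outputs["feature_table"] = tbl_path
        log.success()
        result.stages["export"] = "ok"

        missing = [p for p in result.outputs.values() if not (os.path.exists(p) and os.path.getsize(p))]
        result.status = "complete" if not missing else "failed"
        if missing:
            result.error = f"missing outputs: {missing}"
    except Exception as exc:  # sample isolation: record, never propagate
        current = next((s for s in ("export", "annotate", "standardize", "correct", "select", "assembly") if s not in result.stages), "setup")
        _StageLog(dirs["logs"], current).failure(str(exc))
        result.stages[current] = "failed"
        result.status = "failed"
        result.error = f"{type(exc).__name__}: {exc}"
        if not isinstance(exc, PlastopipeError):
            result.error += "\n" + traceback.format_exc(limit=3)
    return result


def run_batch(samples: list[SampleConfig], outdir: str = ".") -> RunManifest:
    """Run every sample independently and summarize in a manifest."""
    if not samples:
        raise ConfigError("empty batch: no samples to run")
    manifest = RunManifest()
    for sample in samples:
        manifest.results.append(run_sample(sample, outdir))
    manifest_path = os.path.join(outdir, "manifest.tsv")
    with open(manifest_path, "w") as fh:
        fh.write(manifest.report())
    return manifest
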