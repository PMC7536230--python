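"""File formats: BedGraph profiles, BED fragments, annotations, configs.

Profiles are stored as 4-column BedGraph (one file per strand), fragments
and site calls as BED6, annotations as GFF3 (with a part-type column) or
BED6 with ``kind|name`` in the name field.  GFF3 input is converted from
1-based closed to 0-based half-open coordinates explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .part_calling import SiteCall
from .profiles import AlignedFragment, StrandedProfile

__all__ = [
    "Part",
    "CircuitAnnotation",
    "read_bedgraph",
    "write_bedgraph",
    "read_fragments_bed",
    "write_fragments_bed",
    "read_annotation",
    "write_annotation",
    "write_site_calls_bed",
    "load_run_config",
    "run_pipeline",
    "StageError",
]

PART_KINDS = ("promoter", "ribozyme", "rbs", "CDS", "terminator")


@dataclass(frozen=True)
class Part:
    """One genetic part on the circuit DNA (0-based, half-open interval)."""

    name: str
    kind: str
    reference_id: str
    start: int
    end: int
    strand: str
    gate: str = ""

    def __post_init__(self) -> None:
        if self.kind not in PART_KINDS:
            raise ValueError(f"unknown part kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"part {self.name}: invalid interval")
        if self.strand not in ("+", "-"):
            raise ValueError(f"part {self.name}: strand must be '+' or '-'")


@dataclass
class CircuitAnnotation:
    """Ordered parts of the circuit with reference lengths."""

    reference_lengths: dict[str, int]
    parts: list[Part] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.parts = sorted(
            self.parts, key=lambda p: (p.reference_id, p.start, p.end)
        )
        self._validate()

    def _validate(self) -> None:
        cds = {}
        for part in self.parts:
            length = self.reference_lengths.get(part.reference_id)
            if length is None:
                raise ValueError(
                    f"part {part.name}: unknown reference {part.reference_id!r}"
                )
            if part.end > length:
                raise ValueError(f"part {part.name}: interval exceeds reference")
            if part.kind == "CDS":
                key = (part.reference_id, part.strand)
                for other in cds.get(key, []):
                    if part.start < other.end and other.start < part.end:
                        raise ValueError(
                            f"overlapping CDS entries: {other.name} and {part.name}"
                        )
                cds.setdefault(key, []).append(part)

    def of_kind(self, kind: str) -> list[Part]:
        return [p for p in self.parts if p.kind == kind]

    def by_name(self, name: str) -> Part:
        for part in self.parts:
            if part.name == name:
                return part
        raise KeyError(name)

    def for_gate(self, gate: str) -> list[Part]:
        return [p for p in self.parts if p.gate == gate]


# ------------------------------------------------------------------ bedgraph


def write_bedgraph(profile: StrandedProfile, path: str | Path) -> None:
    """Write a profile as 4-column BedGraph, merging equal-value runs."""
    v = profile.values
    with open(path, "w") as fh:
        fh.write(
            f"# reference={profile.reference_id} strand={profile.strand} "
            f"units={profile.units}\n"
        )
        if len(v) == 0:
            return
        boundaries = np.flatnonzero(np.diff(v) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(v)]))
        for s, e in zip(starts, ends):
            fh.write(f"{profile.reference_id}\t{s}\t{e}\t{v[s]:.10g}\n")


def read_bedgraph(path: str | Path) -> StrandedProfile:
    """Read a BedGraph written by :func:`write_bedgraph`."""
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for token in line.lstrip("# ").split():
                    if "=" in token:
                        key, _, val = token.partition("=")
                        meta[key] = val
                continue
            chrom, start, end, value = line.split("\t")
            rows.append((chrom, int(start), int(end), float(value)))
    if not rows:
        raise ValueError(f"{path}: empty BedGraph")
    length = max(end for _, _, end, _ in rows)
    values = np.zeros(length)
    for _, start, end, value in rows:
        values[start:end] = value
    return StrandedProfile(
        reference_id=meta.get("reference", rows[0][0]),
        strand=meta.get("strand", "+"),
        values=values,
        units=meta.get("units", "arb_mrna"),
    )


# ----------------------------------------------------------------- BED6 I/O


def write_fragments_bed(
    fragments: Sequence[AlignedFragment], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for i, frag in enumerate(fragments):
            fh.write(
                f"{frag.reference_id}\t{frag.start}\t{frag.end}\tfrag{i}\t0\t{frag.strand}\n"
            )


def read_fragments_bed(path: str | Path) -> list[AlignedFragment]:
    fragments = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 requires 6 columns")
            ref, start, end, _name, _score, strand = fields[:6]
            fragments.append(AlignedFragment(ref, int(start), int(end), strand))
    return fragments


def write_site_calls_bed(calls: Sequence[SiteCall], reference_id: str, path: str | Path) -> None:
    """Site calls as BED6 with the ratio in the score column."""
    with open(path, "w") as fh:
        for call in calls:
            flags = []
            if call.ribozyme_coincident:
                flags.append("ribozyme")
            if call.pseudo_denominator:
                flags.append("pseudo")
            name = call.kind + ("," + ",".join(flags) if flags else "")
            fh.write(
                f"{reference_id}\t{call.position}\t{call.position + 1}\t"
                f"{name}\t{call.score:.6g}\t{call.strand}\n"
            )


# --------------------------------------------------------------- annotation


def write_annotation(annotation: CircuitAnnotation, path: str | Path) -> None:
    """Write an annotation as GFF3 (1-based closed intervals)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ref, length in sorted(annotation.reference_lengths.items()):
            fh.write(f"##sequence-region {ref} 1 {length}\n")
        for part in annotation.parts:
            attrs = f"Name={part.name}"
            if part.gate:
                attrs += f";gate={part.gate}"
            fh.write(
                f"{part.reference_id}\tcircuitflux\t{part.kind}\t"
                f"{part.start + 1}\t{part.end}\t.\t{part.strand}\t.\t{attrs}\n"
            )


def read_annotation(path: str | Path) -> CircuitAnnotation:
    """Read a circuit annotation from GFF3 or BED6.

    GFF3 coordinates are converted from 1-based closed to 0-based
    half-open.  BED files must carry ``kind|name`` in the name column.
    Unknown part types, out-of-bounds intervals and coordinate-convention
    violations raise errors naming the offending line.
    """
    path = Path(path)
    lengths: dict[str, int] = {}
    parts: list[Part] = []
    is_gff = path.suffix.lower() in (".gff", ".gff3") or _sniff_gff(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                _, ref, _start, end = line.split()
                lengths[ref] = int(end)
                continue
            if line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            try:
                if is_gff:
                    ref, _src, kind, start1, end1, _score, strand, _frame, attrs = (
                        fields[:9]
                    )
                    start, end = int(start1) - 1, int(end1)
                    if int(start1) < 1:
                        raise ValueError("GFF coordinates are 1-based; found 0")
                    attr_map = dict(
                        item.partition("=")[::2] for item in attrs.split(";") if item
                    )
                    name = attr_map.get("Name", f"part{lineno}")
                    gate = attr_map.get("gate", "")
                else:
                    ref, start_s, end_s, name_field, _score, strand = fields[:6]
                    start, end = int(start_s), int(end_s)
                    kind, _, name = name_field.partition("|")
                    gate = ""
                parts.append(
                    Part(
                        name=name,
                        kind=kind,
                        reference_id=ref,
                        start=start,
                        end=end,
                        strand=strand,
                        gate=gate,
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if not lengths:
        for part in parts:
            lengths[part.reference_id] = max(
                lengths.get(part.reference_id, 0), part.end
            )
    try:
        return CircuitAnnotation(reference_lengths=lengths, parts=parts)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def _sniff_gff(path: Path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return first.startswith("##gff")


# ------------------------------------------------------------------- config


REQUIRED_CONFIG_KEYS = ("globals", "sensors", "promoters", "gates")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run the full analysis on a bundle described by ``config``.

    ``config`` carries a ``paths`` block (annotation, per-reference
    fragment BEDs, optional per-reference footprint BEDs and a
    ``flux_calibration`` mapping reference -> built-units per RNAP/s), an
    optional ``window`` block and optional ``constants``.  Emits a part
    table, a gene metric table and a model score report under
    ``out_dir``; any stage failure aborts with the stage name.
    """
    from .metrics import GeneInterval, compute_rd, steady_state_mrna, translation_efficiency
    from .model import CircuitModel
    from .part_calling import (
        WindowConfig,
        call_tss,
        call_tts,
        promoter_strength,
        ribozyme_ce,
        terminator_strength,
    )
    from .profiles import (
        UNIT_RNAP_PER_S_TOTAL,
        StrandedProfile,
        build_transcript_profile,
        map_psites_center_weighted,
        mrna_to_flux,
        normalize_occupancy_absolute,
    )

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = config.get("paths", {})
    constants = config.get("constants", {})
    gamma = float(constants.get("gamma", 0.0067))
    omega = float(constants.get("omega", 15.0))
    window = config.get("window", {})
    cfg = WindowConfig(
        n=int(window.get("n", 10)),
        A=int(window.get("A", 10)),
        ratio_threshold=float(window.get("ratio_threshold", 5.0)),
    )

    try:
        annotation = read_annotation(paths["annotation"])
    except Exception as exc:  # noqa: BLE001 - stage context wrapper
        raise StageError("read_annotation", exc) from exc

    flux_by_ref: dict[str, StrandedProfile] = {}
    fragments_by_ref: dict[str, list] = {}
    try:
        for ref, frag_path in paths.get("fragments", {}).items():
            fragments = read_fragments_bed(frag_path)
            length = annotation.reference_lengths[ref]
            sense, _ = build_transcript_profile(fragments, length, reference_id=ref)
            flux_by_ref[ref] = mrna_to_flux(sense, gamma)
            fragments_by_ref[ref] = fragments
            write_bedgraph(flux_by_ref[ref], out_dir / f"flux_{ref}_plus.bedgraph")
    except Exception as exc:
        raise StageError("profiles", exc) from exc

    part_rows = []
    try:
        for ref, flux in flux_by_ref.items():
            tss_calls = call_tss(flux, cfg)
            tts_calls = call_tts(flux, cfg)
            for part in annotation.parts:
                if part.reference_id != ref or part.strand != "+":
                    continue
                if part.kind == "promoter":
                    near = [c for c in tss_calls if abs(c.position - part.end) <= 11]
                    value = (
                        promoter_strength(flux, near[0], cfg) if near else None
                    )
                    part_rows.append(
                        {"part": part.name, "kind": "promoter", "value": value,
                         "units": flux.units}
                    )
                elif part.kind == "terminator":
                    near = [c for c in tts_calls if abs(c.position - part.start) <= 3]
                    value = (
                        terminator_strength(flux, near[0], cfg) if near else None
                    )
                    part_rows.append(
                        {"part": part.name, "kind": "terminator", "value": value,
                         "units": "fold"}
                    )
                elif part.kind == "ribozyme":
                    result = ribozyme_ce(fragments_by_ref[ref], part.end, "+")
                    part_rows.append(
                        {"part": part.name, "kind": "ribozyme", "value": result.ce,
                         "units": "fraction"}
                    )
        pd.DataFrame(part_rows).to_csv(out_dir / "parts.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("part_calling", exc) from exc

    gene_rows = []
    try:
        footprint_paths = paths.get("footprints", {})
        calibration = paths.get("flux_calibration", {})
        if footprint_paths:
            mapped = []
            for ref, fp_path in footprint_paths.items():
                footprints = read_fragments_bed(fp_path)
                length = annotation.reference_lengths.get(ref) or (
                    max(f.end for f in footprints) + 100
                )
                sense, anti = map_psites_center_weighted(
                    footprints, length, reference_id=ref
                )
                mapped.extend([sense, anti])
            occupancies = normalize_occupancy_absolute(mapped)
            for part in annotation.of_kind("CDS"):
                occ = next(
                    (
                        p
                        for p in occupancies
                        if p.reference_id == part.reference_id
                        and p.strand == part.strand
                    ),
                    None,
                )
                if occ is None:
                    continue
                gene = GeneInterval(
                    part.reference_id, part.start, part.end, part.strand
                )
                rd = compute_rd(occ, gene)
                row = {"gene": part.name, "rd": rd}
                scale = calibration.get(part.reference_id)
                if scale and part.reference_id in flux_by_ref:
                    absolute = StrandedProfile(
                        part.reference_id,
                        "+",
                        flux_by_ref[part.reference_id].values / float(scale),
                        UNIT_RNAP_PER_S_TOTAL,
                    )
                    row["m_ss"] = steady_state_mrna(absolute, gene, gamma)
                    row["te"] = translation_efficiency(
                        rd, row["m_ss"]
                    )
                gene_rows.append(row)
            pd.DataFrame(gene_rows).to_csv(
                out_dir / "genes.tsv", sep="\t", index=False
            )
    except Exception as exc:
        raise StageError("expression_metrics", exc) from exc

    try:
        model_path = paths.get("model")
        model = CircuitModel.from_yaml(model_path) if model_path else CircuitModel.nominal()
        truth = model.designed_truth_table()
        outputs = model.output_steady_states()
        report = {
            "score": model.circuit_score(),
            "truth_table": {
                "".join(map(str, s)): bit for s, bit in truth.items()
            },
            "steady_states": {
                "".join(map(str, s)): value for s, value in outputs.items()
            },
            "parts": len(part_rows),
            "genes": len(gene_rows),
        }
        import json as _json

        (out_dir / "report.json").write_text(_json.dumps(report, indent=2) + "\n")
    except Exception as exc:
        raise StageError("circuit_model", exc) from exc
    return report


def load_run_config(path: str | Path) -> dict:
    """Load and schema-check a run configuration YAML before any compute."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"{path}: config must be a mapping")
    missing = [key for key in REQUIRED_CONFIG_KEYS if key not in config]
    if missing:
        raise ValueError(f"{path}: missing config sections {missing}")
    for name, value in config.get("globals", {}).items():
        if not isinstance(value, (int, float)) or value <= 0:
            raise ValueError(f"{path}: globals.{name} must be a positive number")
    for path_key in ("profiles", "fragments", "annotation"):
        ref = config.get("paths", {}).get(path_key)
        if ref is not None and not Path(ref).exists():
            raise FileNotFoundError(f"{path}: paths.{path_key} -> {ref} not found")
    return config
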