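"""Ground-truth-known synthetic data generation.

The forward model decomposes each circuit state into *transcript classes*:
maximal (start, end, weight) intervals of RNA molecules produced by one
promoter, after ribozyme cleavage branching and partial terminator
read-through.  Noise-free flux profiles and Poisson fragment samples are
both derived from the same class decomposition, so sampled coverage
converges to the forward profile by construction, with sharp steps at
transcript boundaries (the end-enriched library behaviour the analysis
relies on).

Fragment sampling within a class draws a length L uniformly from the
library range and a virtual start uniformly from [start-L+1, end-1],
truncating the fragment to the class interval: every nucleotide of the
class is then covered with equal probability, and truncated fragments
pile up at class boundaries exactly like cleavage/termination products.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CircuitAnnotation, Part
from .metrics import DecayModel, GeneInterval
from .model import CircuitModel
from .profiles import (
    ANTISENSE,
    SENSE,
    UNIT_ARB_MRNA,
    UNIT_RIBOSOMES,
    UNIT_RNAP_PER_S_TOTAL,
    FragmentArray,
    StrandedProfile,
)

__all__ = [
    "TranscriptClass",
    "GroundTruth",
    "SyntheticBundle",
    "nominal_annotation",
    "transcript_classes",
    "forward_flux",
    "sample_fragments",
    "forward_occupancy",
    "generate_genome_background",
    "generate_bundle",
]

FRAGMENT_RANGE = (10, 45)
FOOTPRINT_RANGE = (23, 42)
RIBOZYME_LOST_NT = 15  # 5' cleavage products at most this long are lost


@dataclass(frozen=True)
class TranscriptClass:
    """One population of identical RNA molecules."""

    reference_id: str
    strand: str
    start: int
    end: int
    weight: float  # abundance in flux units (RNAP/s per cell)


@dataclass
class GroundTruth:
    """Everything planted into a synthetic bundle."""

    state: tuple[int, int, int]
    seed: int
    activities: dict[str, float]  # promoter -> per-cell RNAP/s
    tss: dict[str, dict]  # promoter -> {position, strand, reference}
    ribozymes: dict[str, dict]  # name -> {site, eta, strand, reference, gate}
    terminators: dict[str, dict]  # name -> {position, T, strand, reference, gate}
    genes: dict[str, dict]  # gate -> {start, end, strand, reference, alpha, m_ss, rd}
    flux_scale: dict[str, float]  # reference -> built-units per RNAP/s


@dataclass
class SyntheticBundle:
    annotation: CircuitAnnotation
    truth: GroundTruth
    flux: dict[tuple[str, str], StrandedProfile]  # noise-free, RNAP/s totals
    fragments: dict[str, FragmentArray]
    footprints: dict[str, FragmentArray]
    occupancy: dict[tuple[str, str], StrandedProfile]  # noise-free, ribosomes
    genome_genes: pd.DataFrame | None = None


# ------------------------------------------------------------- annotation


def _gate_block(
    gate: dict, offset: int, reference_id: str
) -> tuple[list[Part], int]:
    """Lay out one transcription unit; returns its parts and total length."""
    name = gate["name"]
    inputs = gate["inputs"]
    parts: list[Part] = []
    pos = offset
    for prom in inputs:
        parts.append(
            Part(prom, "promoter", reference_id, pos, pos + 30, "+", gate=name)
        )
        pos += 40
    tss_last = pos - 10  # TSS of the last promoter = its part end
    site = tss_last + 10
    parts.append(
        Part(gate["ribozyme"], "ribozyme", reference_id, site - 10, site, "+", gate=name)
    )
    parts.append(Part(gate["rbs"], "rbs", reference_id, site, site + 20, "+", gate=name))
    cds_start = site + 30
    cds_end = cds_start + 600
    parts.append(
        Part(name, "CDS", reference_id, cds_start, cds_end, "+", gate=name)
    )
    tts = cds_end + 30
    parts.append(
        Part(gate["terminator"], "terminator", reference_id, tts, tts + 25, "+", gate=name)
    )
    return parts, (tts + 25 + 35) - offset


def tss_of(part: Part) -> int:
    """Transcription start position implied by a promoter part."""
    return part.end if part.strand == SENSE else part.start


def cleavage_site_of(part: Part) -> int:
    return part.end if part.strand == SENSE else part.start


def tts_of(part: Part) -> int:
    return part.start if part.strand == SENSE else part.end


def nominal_annotation(config: dict | None = None) -> CircuitAnnotation:
    """Synthetic coordinates for the nominal circuit and output plasmids.

    Gate transcription units are laid out in their physical DNA order on
    the ``circuit`` reference (all sense strand), with the reporter unit
    on the separate ``output`` reference.
    """
    if config is None:
        from .model import load_nominal_config

        config = load_nominal_config()
    gates = config["gates"]
    parts: list[Part] = []
    offset = 100
    for gate in gates[:-1]:
        block, length = _gate_block(gate, offset, "circuit")
        parts.extend(block)
        offset += length
    circuit_len = offset + 100
    block, length = _gate_block(gates[-1], 100, "output")
    parts.extend(block)
    output_len = 100 + length + 100
    return CircuitAnnotation(
        reference_lengths={"circuit": circuit_len, "output": output_len},
        parts=parts,
    )


# ------------------------------------------------------------ forward model


def transcript_classes(
    annotation: CircuitAnnotation,
    activities: Mapping[str, float],
    ribozyme_eta: Mapping[str, float],
    terminator_T: Mapping[str, float],
) -> list[TranscriptClass]:
    """Decompose a circuit state into transcript classes.

    Every promoter with an activity launches transcripts at its TSS; each
    downstream ribozyme splits every branch (the short 5' product of the
    immediately upstream promoter is discarded as lost in library prep),
    and each terminator ends a (1 - 1/T) fraction of every branch.
    """
    classes: list[TranscriptClass] = []
    for ref, length in annotation.reference_lengths.items():
        for strand in (SENSE, ANTISENSE):
            proms = [
                p
                for p in annotation.parts
                if p.reference_id == ref and p.strand == strand and p.kind == "promoter"
            ]
            events = [
                p
                for p in annotation.parts
                if p.reference_id == ref
                and p.strand == strand
                and p.kind in ("ribozyme", "terminator")
            ]
            for prom in proms:
                weight = float(activities.get(prom.name, 0.0))
                if weight <= 0:
                    continue
                start = tss_of(prom)
                downstream = sorted(
                    events,
                    key=lambda p: cleavage_site_of(p)
                    if p.kind == "ribozyme"
                    else tts_of(p),
                    reverse=(strand == ANTISENSE),
                )
                branches = [(start, weight)]
                for event in downstream:
                    pos = (
                        cleavage_site_of(event)
                        if event.kind == "ribozyme"
                        else tts_of(event)
                    )
                    if (strand == SENSE and pos <= start) or (
                        strand == ANTISENSE and pos >= start
                    ):
                        continue
                    new_branches = []
                    for bstart, bweight in branches:
                        if event.kind == "ribozyme":
                            eta = float(ribozyme_eta[event.name])
                            w_cut = bweight * eta
                            piece_len = abs(pos - bstart)
                            if piece_len > RIBOZYME_LOST_NT and w_cut > 0:
                                lo, hi = sorted((bstart, pos))
                                classes.append(
                                    TranscriptClass(ref, strand, lo, hi, w_cut)
                                )
                            if w_cut > 0:
                                new_branches.append((pos, w_cut))
                            if bweight - w_cut > 0:
                                new_branches.append((bstart, bweight - w_cut))
                        else:
                            T = float(terminator_T[event.name])
                            w_stop = bweight * (1.0 - 1.0 / T)
                            if w_stop > 0:
                                lo, hi = sorted((bstart, pos))
                                classes.append(
                                    TranscriptClass(ref, strand, lo, hi, w_stop)
                                )
                            if bweight / T > 0:
                                new_branches.append((bstart, bweight / T))
                    branches = new_branches
                for bstart, bweight in branches:
                    lo, hi = (bstart, length) if strand == SENSE else (0, bstart)
                    if hi > lo and bweight > 0:
                        classes.append(TranscriptClass(ref, strand, lo, hi, bweight))
    return classes


def forward_flux(
    classes: Sequence[TranscriptClass],
    reference_lengths: Mapping[str, int],
) -> dict[tuple[str, str], StrandedProfile]:
    """Noise-free flux profiles (per-cell RNAP/s) from transcript classes."""
    out: dict[tuple[str, str], StrandedProfile] = {}
    for ref, length in reference_lengths.items():
        for strand in (SENSE, ANTISENSE):
            diff = np.zeros(length + 1)
            for cls in classes:
                if cls.reference_id == ref and cls.strand == strand:
                    diff[cls.start] += cls.weight
                    diff[cls.end] -= cls.weight
            out[(ref, strand)] = StrandedProfile(
                ref, strand, np.cumsum(diff[:-1]), UNIT_RNAP_PER_S_TOTAL
            )
    return out


# ---------------------------------------------------------------- sampling


def _mean_truncated_length(span: int, lengths: np.ndarray) -> float:
    return float(np.mean(lengths * span / (span + lengths - 1.0)))


def sample_fragments(
    classes: Sequence[TranscriptClass],
    depth: float,
    rng: np.random.Generator,
    length_range: tuple[int, int] = FRAGMENT_RANGE,
) -> dict[str, FragmentArray]:
    """Sample ~``depth`` fragments with coverage proportional to class weight.

    Fragment totals are Poisson; within a class, every nucleotide has
    identical expected coverage and fragments truncate sharply at class
    boundaries (transcript 5'/3' ends and cleavage sites).
    """
    lo, hi = length_range
    all_lengths = np.arange(lo, hi + 1, dtype=float)
    usable = [c for c in classes if c.weight > 0 and c.end > c.start]
    if not usable:
        return {}
    rates = np.array(
        [
            c.weight
            * (c.end - c.start)
            / _mean_truncated_length(c.end - c.start, all_lengths)
            for c in usable
        ]
    )
    rates *= depth / rates.sum()
    columns: dict[str, list] = {}
    for cls, rate in zip(usable, rates):
        n = int(rng.poisson(rate))
        if n == 0:
            continue
        L = rng.integers(lo, hi + 1, size=n)
        span = cls.end - cls.start
        virtual = cls.start - L + 1 + rng.integers(0, span + L - 1, size=n)
        starts = np.maximum(virtual, cls.start)
        ends = np.minimum(virtual + L, cls.end)
        ok = ends > starts
        cols = columns.setdefault(cls.reference_id, [[], [], []])
        cols[0].append(starts[ok])
        cols[1].append(ends[ok])
        cols[2].append(np.full(int(ok.sum()), cls.strand == SENSE))
    return {
        ref: FragmentArray(
            ref,
            np.concatenate(cols[0]),
            np.concatenate(cols[1]),
            np.concatenate(cols[2]),
        )
        for ref, cols in columns.items()
    }


# -------------------------------------------------------------- occupancy


def forward_occupancy(
    genes: Sequence[tuple[GeneInterval, float, float]],
    reference_lengths: Mapping[str, int],
    rng: np.random.Generator,
    footprints_per_ribosome: float = 50.0,
    elevation: DecayModel | None = None,
    length_range: tuple[int, int] = FOOTPRINT_RANGE,
    trim: int = 11,
) -> tuple[dict[str, FragmentArray], dict[tuple[str, str], StrandedProfile]]:
    """Plant ribosome occupancy and sample footprints reproducing it.

    ``genes`` holds (interval, alpha, m_ss) triples; the expected
    occupancy over a CDS is alpha * m_ss / omega ribosomes per nucleotide
    spread uniformly (times the optional 5' elevation model).  Sampled
    footprints reconstruct the planted profile in expectation under
    center-weighted P-site mapping.
    """
    omega = 15.0
    lo, hi = length_range
    occ: dict[tuple[str, str], np.ndarray] = {
        (ref, strand): np.zeros(length)
        for ref, length in reference_lengths.items()
        for strand in (SENSE, ANTISENSE)
    }
    columns: dict[str, list] = {}
    for gene, alpha, m_ss in genes:
        length = gene.end - gene.start
        density = alpha * m_ss / omega
        profile = np.full(length, density)
        if elevation is not None:
            d = np.arange(length, dtype=float)
            if gene.strand == ANTISENSE:
                d = d[::-1]
            profile = profile * np.asarray(elevation(d), dtype=float)
        occ[(gene.reference_id, gene.strand)][gene.start : gene.end] += profile
        total = profile.sum()
        n = int(rng.poisson(total * footprints_per_ribosome))
        if n == 0:
            continue
        if elevation is None:
            anchors = gene.start + rng.integers(0, length, size=n)
        else:
            anchors = gene.start + rng.choice(length, size=n, p=profile / total)
        L = rng.integers(lo, hi + 1, size=n)
        offset = rng.integers(0, L - 2 * trim, size=n)
        starts = anchors - trim - offset
        ends = starts + L
        ref_len = reference_lengths[gene.reference_id]
        ok = (starts >= 0) & (ends <= ref_len)
        cols = columns.setdefault(gene.reference_id, [[], [], []])
        cols[0].append(starts[ok])
        cols[1].append(ends[ok])
        cols[2].append(np.full(int(ok.sum()), gene.strand == SENSE))
    footprints = {
        ref: FragmentArray(
            ref,
            np.concatenate(cols[0]),
            np.concatenate(cols[1]),
            np.concatenate(cols[2]),
        )
        for ref, cols in columns.items()
    }
    profiles = {
        key: StrandedProfile(key[0], key[1], values, UNIT_RIBOSOMES)
        for key, values in occ.items()
    }
    return footprints, profiles


# ------------------------------------------------------------------ genome


def generate_genome_background(
    n_genes: int,
    rng: np.random.Generator,
    fpkm_lognorm: tuple[float, float] = (1.0, 1.0),
    rd_lognorm: tuple[float, float] = (-1.5, 1.0),
    mw_range: tuple[float, float] = (20000.0, 120000.0),
    gene_length: int = 600,
    spacing: int = 300,
    planted_responders: Sequence[tuple[str, float]] = (),
    states: Sequence[str] = (),
    repressor_on_states: Sequence[str] = (),
) -> tuple[pd.DataFrame, dict[tuple[str, str], StrandedProfile], StrandedProfile]:
    """Background genome gene set with log-normal expression draws.

    ``planted_responders`` lists (gene_name, fold_repression) pairs whose
    RD is divided by the fold in the ``repressor_on_states`` subset of
    ``states``, emulating off-target repression.  Returns the gene table,
    the RNA profiles and the occupancy profile.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    pitch = gene_length + spacing
    length = n_genes * pitch + spacing
    rows = []
    rna = np.zeros(length)
    occ = np.zeros(length)
    fpkm = rng.lognormal(*fpkm_lognorm, size=n_genes)
    rd = rng.lognormal(*rd_lognorm, size=n_genes)
    mw = rng.uniform(*mw_range, size=n_genes)
    responder_fold = dict(planted_responders)
    for i in range(n_genes):
        start = spacing + i * pitch
        end = start + gene_length
        name = f"g{i:04d}"
        rna[start:end] = fpkm[i]
        occ[start:end] = rd[i]
        row = {
            "name": name,
            "reference_id": "genome",
            "start": start,
            "end": end,
            "strand": "+",
            "fpkm": fpkm[i],
            "rd": rd[i],
            "mw": mw[i],
        }
        fold = responder_fold.get(name)
        on = set(repressor_on_states)
        for state in states:
            repressed = fold is not None and state in on
            row[f"rd_{state}"] = rd[i] / fold if repressed else rd[i]
        rows.append(row)
    profiles = {
        ("genome", SENSE): StrandedProfile("genome", SENSE, rna, UNIT_ARB_MRNA),
        ("genome", ANTISENSE): StrandedProfile(
            "genome", ANTISENSE, np.zeros(length), UNIT_ARB_MRNA
        ),
    }
    occ_profile = StrandedProfile("genome", SENSE, occ, UNIT_RIBOSOMES)
    return pd.DataFrame(rows), profiles, occ_profile


# ------------------------------------------------------------------ bundle


def generate_bundle(
    model: CircuitModel,
    state: tuple[int, int, int],
    seed: int,
    depth: float = 1e6,
    footprints_per_ribosome: float = 50.0,
    sample_footprints: bool = True,
) -> SyntheticBundle:
    """Generate one full circuit-state bundle with known ground truth."""
    rng = np.random.default_rng(seed)
    config = model.config
    annotation = nominal_annotation(config)

    _, R, y = model.steady_state(state)
    sensor_values = model.sensor_values(state)
    activities: dict[str, float] = dict(sensor_values)
    for i, prom in enumerate(model.promoter_of_gate):
        if prom is not None:
            activities[prom] = float(y[i])

    ribozyme_eta = {k: float(v) for k, v in config["ribozymes"].items()}
    terminator_T = {k: float(v) for k, v in config["terminators"].items()}
    classes = transcript_classes(annotation, activities, ribozyme_eta, terminator_T)
    flux = forward_flux(classes, annotation.reference_lengths)

    fragments = sample_fragments(classes, depth, rng)

    # planted per-gene translation: occupancy consistent with TE = alpha
    gamma = model.gamma
    genes: dict[str, dict] = {}
    gene_triples = []
    for gate in config["gates"]:
        cds = next(
            p for p in annotation.parts if p.kind == "CDS" and p.gate == gate["name"]
        )
        prof = flux[(cds.reference_id, cds.strand)]
        if cds.strand == SENSE:
            window = prof.values[cds.end - 10 : cds.end]
        else:
            window = prof.values[cds.start : cds.start + 10]
        m_ss = float(window.mean()) / gamma
        alpha = float(config["rbs"][gate["rbs"]])
        interval = GeneInterval(cds.reference_id, cds.start, cds.end, cds.strand)
        gene_triples.append((interval, alpha, m_ss))
        genes[gate["name"]] = {
            "reference": cds.reference_id,
            "start": cds.start,
            "end": cds.end,
            "strand": cds.strand,
            "alpha": alpha,
            "m_ss": m_ss,
            "rd": alpha * m_ss / 15.0,
        }

    footprints: dict[str, FragmentArray] = {}
    occupancy: dict[tuple[str, str], StrandedProfile] = {}
    if sample_footprints:
        # pad with a flat genome occupancy so that the planted global total
        # equals the cell's active-ribosome count; the analysis then
        # recovers absolute occupancies through the 20,000 normalization
        total_ribosomes = 20000.0
        circuit_ribosomes = sum(
            alpha * m_ss / 15.0 * (g.end - g.start) for g, alpha, m_ss in gene_triples
        )
        genome_len = 30000
        filler_density = (total_ribosomes - circuit_ribosomes) / genome_len
        if filler_density <= 0:
            raise ValueError("circuit occupancy exceeds the total ribosome pool")
        ref_lengths = dict(annotation.reference_lengths)
        ref_lengths["genome"] = genome_len
        filler = (
            GeneInterval("genome", 0, genome_len, SENSE),
            filler_density * 15.0,  # alpha chosen so alpha*m_ss/omega = density
            1.0,
        )
        footprints, occupancy = forward_occupancy(
            gene_triples + [filler],
            ref_lengths,
            rng,
            footprints_per_ribosome=footprints_per_ribosome,
        )

    tss: dict[str, dict] = {}
    ribozymes: dict[str, dict] = {}
    terminators: dict[str, dict] = {}
    for part in annotation.parts:
        entry = {
            "reference": part.reference_id,
            "strand": part.strand,
            "gate": part.gate,
        }
        if part.kind == "promoter":
            tss[part.name] = {**entry, "position": tss_of(part)}
        elif part.kind == "ribozyme":
            ribozymes[part.name] = {
                **entry,
                "site": cleavage_site_of(part),
                "eta": ribozyme_eta[part.name],
            }
        elif part.kind == "terminator":
            terminators[part.name] = {
                **entry,
                "position": tts_of(part),
                "T": terminator_T[part.name],
            }

    flux_scale = {}
    for ref in annotation.reference_lengths:
        mass = sum(
            float(p.values.sum()) for key, p in flux.items() if key[0] == ref
        )
        flux_scale[ref] = gamma * 1e9 / mass if mass > 0 else float("nan")

    truth = GroundTruth(
        state=tuple(state),
        seed=seed,
        activities=activities,
        tss=tss,
        ribozymes=ribozymes,
        terminators=terminators,
        genes=genes,
        flux_scale=flux_scale,
    )
    return SyntheticBundle(
        annotation=annotation,
        truth=truth,
        flux=flux,
        fragments=fragments,
        footprints=footprints,
        occupancy=occupancy,
    )
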