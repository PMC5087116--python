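"""Synthetic EMS chromosome-sequencing experiments.

Generates everything the pipeline consumes — a repeat-masked reference
assembly, per-line mutant genomes, mpileup-style read columns and a
machine-readable truth table — so every stage is testable without external
sequencing data.

What is emulated
----------------
* a contig set with log-normally distributed lengths (truncated at a 500 bp
  floor, matching the assembly's reporting cutoff), i.i.d. bases at a
  configurable GC content, and a configurable fraction of repeat-masked
  (lowercase) positions laid down in contiguous blocks;
* per-line canonical EMS mutagenesis: each unmasked G/C site independently
  mutated (G→A, C→T only) so that the genome-wide density matches the
  configured mutations-per-callable-bp rate (observed range in real
  experiments: roughly one per 380–741 kb);
* one planted causal contig carrying an independent canonical lesion in
  every mutant line, at distinct positions;
* an optional cultivar-contaminant line with all-spectrum natural variation
  at high density (~1 per 1,580 bp);
* an optional chimeric assembly-artifact contig whose second half diverges
  ~1 % from the sequence every line (including the wild type) actually
  carries;
* read columns with Poisson depth (default mean 30, within the 27–35×
  range of real runs) and uniform per-base miscall error.

Pileup columns are synthesized directly from the mutant genomes — no read
simulation or alignment — because the pipeline consumes mpileup and mapping
is out of scope. Mutagenesis is per-site Bernoulli, which makes the
analytic false-positive model exact by construction.

Determinism: one master seed drives reference construction and causal/
artifact placement; each line's mutagenesis stream is seeded as
``seed + line_index`` and its pileup stream as ``seed + 10000 + line_index``,
so identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ValidationError
from .formats_io import PileupColumn, ReferenceContig, write_fasta, write_mpileup
from .snv_caller import MutantCallSet, SnvCall, is_canonical

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_EMS_ALT = {"G": "A", "C": "T"}
_NON_REF = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}

CLASS_CAUSAL = "causal"
CLASS_BACKGROUND = "background"
CLASS_NATURAL = "natural"

WILDTYPE_ID = "wildtype"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of one synthetic experiment.

    Defaults mirror the conditions of a six-mutant chromosome-sequencing
    screen: ~5 Mb of assembly in 600 contigs, GC 0.44, 10 % repeat-masked,
    a 10-kb causal contig, background density 1/500,000 per callable bp
    (the middle of the observed 1/380k–1/741k range), 30× Poisson coverage
    and error-free reads.
    """

    seed: int = 1
    n_contigs: int = 600
    contig_length_median: float = 7000.0
    contig_length_sigma: float = 0.6
    min_contig_length: int = 500
    gc_content: float = 0.44
    masked_fraction: float = 0.1
    causal_length: int = 10_000
    n_mutants: int = 6
    background_density: float = 1.0 / 500_000
    contaminant: bool = False
    contaminant_density: float = 1.0 / 1580
    coverage_lambda: float = 30.0
    error_rate: float = 0.0
    artifact_contig: bool = False
    artifact_divergence: float = 0.01
    wildtype_pileup: bool = False

    def __post_init__(self) -> None:
        for name in ("gc_content", "masked_fraction", "error_rate", "artifact_divergence"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.causal_length < 1000:
            raise ConfigError(f"causal_length must be ≥ 1000, got {self.causal_length}")
        if self.n_mutants < 1:
            raise ConfigError(f"n_mutants must be ≥ 1, got {self.n_mutants}")
        if self.n_contigs < 1:
            raise ConfigError("n_contigs must be ≥ 1")
        if self.background_density < 0 or self.contaminant_density < 0:
            raise ConfigError("densities must be non-negative")
        if self.coverage_lambda <= 0:
            raise ConfigError("coverage_lambda must be positive")


class TruthEntry(NamedTuple):
    """One planted mutation."""

    mutant_id: str
    contig_id: str
    position: int  # 1-based
    ref: str
    alt: str
    cls: str  # causal | background | natural


@dataclass
class TruthTable:
    causal_contig_id: str
    entries: list
    contaminant_ids: set = field(default_factory=set)
    artifact_contig_ids: set = field(default_factory=set)

    def by_mutant(self) -> dict:
        out: dict = {}
        for e in self.entries:
            out.setdefault(e.mutant_id, []).append(e)
        return out


# ---------------------------------------------------------------------------
# Reference construction


def _random_sequence(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def _mask_blocks(arr: np.ndarray, fraction: float, rng: np.random.Generator) -> None:
    """Lowercase ~``fraction`` of positions in contiguous blocks, in place."""
    length = arr.size
    target = int(round(fraction * length))
    if target <= 0:
        return
    lowered = np.zeros(length, dtype=bool)
    n_lowered = 0
    while n_lowered < target:
        block = int(rng.integers(100, 501))
        block = min(block, target - n_lowered + 50, length)
        start = int(rng.integers(0, max(1, length - block + 1)))
        segment = lowered[start : start + block]
        n_lowered += int(block - segment.sum())
        segment[:] = True
    arr[lowered] |= 0x20  # ASCII lowercase bit


def make_reference(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[list, str]:
    """Build the synthetic assembly; returns (contigs, causal_contig_id).

    Contig lengths are log-normal (median, sigma) truncated below
    ``min_contig_length`` by resampling; one contig, chosen at random, is
    replaced by the causal contig of ``causal_length``. Deterministic for a
    given seed/rng.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_contigs
    mean_log = np.log(config.contig_length_median)
    lengths = rng.lognormal(mean=mean_log, sigma=config.contig_length_sigma, size=n)
    while True:
        short = lengths < config.min_contig_length
        if not short.any():
            break
        lengths[short] = rng.lognormal(mean_log, config.contig_length_sigma, int(short.sum()))
    lengths = lengths.astype(np.int64)
    causal_idx = int(rng.integers(n))
    lengths[causal_idx] = config.causal_length

    contigs = []
    width = max(5, len(str(n)))
    for i, length in enumerate(lengths):
        arr = _random_sequence(int(length), config.gc_content, rng)
        _mask_blocks(arr, config.masked_fraction, rng)
        contigs.append(ReferenceContig(f"contig_{i:0{width}d}", arr.tobytes().decode("ascii")))
    return contigs, contigs[causal_idx].id


# ---------------------------------------------------------------------------
# Mutagenesis


def _as_arrays(reference: Sequence[ReferenceContig]) -> dict:
    return {
        c.id: np.frombuffer(c.sequence.encode("ascii"), dtype=np.uint8).copy()
        for c in reference
    }


def mutagenize_ems(
    reference: Sequence[ReferenceContig],
    density: float,
    rng: np.random.Generator,
) -> Tuple[dict, list]:
    """Canonical EMS mutagenesis of one line.

    Each unmasked G/C site is mutated independently with probability
    density / g, where g is the genome-wide unmasked G/C fraction, so the
    expected genome-wide count is density × unmasked bases. Returns
    (genome as contig_id → uint8 array, list of (contig_id, pos, ref, alt)).
    """
    if density < 0:
        raise ConfigError("density must be non-negative")
    total_unmasked = sum(c.unmasked_bases for c in reference)
    total_gc = sum(c.gc_unmasked for c in reference)
    if total_gc == 0:
        raise ConfigError("reference has no unmasked G/C sites")
    g = total_gc / total_unmasked
    p_site = density / g
    if p_site > 1:
        raise ConfigError(f"density/g = {p_site:.3g} exceeds 1: density too high")

    genome = _as_arrays(reference)
    entries = []
    for contig in reference:
        arr = genome[contig.id]
        gc_idx = np.nonzero((arr == ord("G")) | (arr == ord("C")))[0]
        if gc_idx.size == 0:
            continue
        hits = gc_idx[rng.random(gc_idx.size) < p_site]
        for i in hits.tolist():
            ref = chr(arr[i])
            alt = _EMS_ALT[ref]
            arr[i] = ord(alt)
            entries.append((contig.id, i + 1, ref, alt))
    return genome, entries


def plant_causal(
    genomes: dict,
    causal_contig: ReferenceContig,
    rng: np.random.Generator,
) -> dict:
    """Give every mutant one extra canonical lesion on the causal contig.

    Positions are distinct unmasked G/C sites sampled without replacement
    across mutants. ``genomes`` maps mutant_id → {contig_id → uint8 array};
    returns mutant_id → (contig_id, pos, ref, alt).
    """
    ref_arr = np.frombuffer(causal_contig.sequence.encode("ascii"), dtype=np.uint8)
    sites = np.nonzero((ref_arr == ord("G")) | (ref_arr == ord("C")))[0]
    mutant_ids = sorted(genomes)
    if sites.size < len(mutant_ids):
        raise ConfigError(
            f"causal contig has {sites.size} unmasked G/C sites; "
            f"need ≥ {len(mutant_ids)}"
        )
    positions = rng.choice(sites, size=len(mutant_ids), replace=False)
    out = {}
    for mutant_id, i in zip(mutant_ids, positions.tolist()):
        arr = genomes[mutant_id][causal_contig.id]
        ref = chr(ref_arr[i])
        alt = _EMS_ALT[ref]
        arr[i] = ord(alt)
        out[mutant_id] = (causal_contig.id, i + 1, ref, alt)
    return out


def mutagenize_natural(
    reference: Sequence[ReferenceContig],
    density: float,
    rng: np.random.Generator,
) -> Tuple[dict, list]:
    """All-spectrum natural variation (cultivar contaminant model).

    Each unmasked site is substituted independently with probability
    ``density``; the alternate is uniform over the three non-reference bases.
    """
    if density < 0:
        raise ConfigError("density must be non-negative")
    genome = _as_arrays(reference)
    entries = []
    for contig in reference:
        arr = genome[contig.id]
        unmasked = np.nonzero(
            (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
        )[0]
        if unmasked.size == 0:
            continue
        hits = unmasked[rng.random(unmasked.size) < density]
        picks = rng.integers(0, 3, size=hits.size)
        for i, k in zip(hits.tolist(), picks.tolist()):
            ref = chr(arr[i])
            alt = _NON_REF[ref][k]
            arr[i] = ord(alt)
            entries.append((contig.id, i + 1, ref, alt))
    return genome, entries


# ---------------------------------------------------------------------------
# Pileup synthesis


def simulate_pileup(
    ref_contig: ReferenceContig,
    mutant_seq: str,
    coverage_lambda: float,
    error_rate: float,
    rng: np.random.Generator,
) -> Iterator[PileupColumn]:
    """Yield read columns for one contig of one line.

    Depth is Poisson(coverage_lambda) per position; each read reports the
    line's base with probability 1 − error_rate, otherwise one of the other
    three bases uniformly. Zero-depth positions are omitted, matching
    samtools behaviour. Columns are keyed to the (uppercased) reference base.
    """
    length = ref_contig.length
    if len(mutant_seq) != length:
        raise ValidationError(
            f"{ref_contig.id}: mutant sequence length {len(mutant_seq)} != {length}"
        )
    refu = ref_contig.sequence.upper()
    mut = mutant_seq.upper()
    cid = ref_contig.id
    depths = rng.poisson(coverage_lambda, length)
    if error_rate > 0:
        n_err = rng.binomial(depths, error_rate)
        err_list = n_err.tolist()
    else:
        err_list = None
    depth_list = depths.tolist()

    for i, d in enumerate(depth_list):
        if d == 0:
            continue
        b = mut[i]
        if err_list is None:
            counts = {b: d}
        else:
            e = err_list[i]
            if e == 0:
                counts = {b: d}
            else:
                counts = {b: d - e} if d > e else {}
                others = _NON_REF.get(b, ["A", "C", "G"])
                for k in rng.integers(0, 3, size=e).tolist():
                    o = others[k]
                    counts[o] = counts.get(o, 0) + 1
        yield PileupColumn(cid, i + 1, refu[i], d, counts)


# ---------------------------------------------------------------------------
# Whole experiments


@dataclass
class Experiment:
    """In-memory result of one simulation run."""

    config: SimulationConfig
    reference: list  # of ReferenceContig
    ems_mutant_ids: list
    contaminant_id: Optional[str]
    genomes: dict  # line_id -> {contig_id -> str}
    wildtype_genome: Optional[dict]
    truth: TruthTable

    @property
    def line_ids(self) -> list:
        return self.ems_mutant_ids + ([self.contaminant_id] if self.contaminant_id else [])

    def pileup_columns(self, line_id: str) -> Iterator[PileupColumn]:
        """Stream this line's pileup over all contigs, reference order."""
        cfg = self.config
        if line_id == WILDTYPE_ID:
            idx = 0
            genome = self.wildtype_genome or {
                c.id: c.sequence for c in self.reference
            }
        else:
            idx = self.line_ids.index(line_id) + 1
            genome = self.genomes[line_id]
        rng = np.random.default_rng(cfg.seed + 10_000 + idx)
        for contig in self.reference:
            yield from simulate_pileup(
                contig, genome[contig.id], cfg.coverage_lambda, cfg.error_rate, rng
            )


def simulate(config: SimulationConfig) -> Experiment:
    """Run the full generative model in memory."""
    master = np.random.default_rng(config.seed)
    reference, causal_id = make_reference(config, master)
    index = {c.id: c for c in reference}
    causal = index[causal_id]

    ems_ids = [f"mut{i:02d}" for i in range(1, config.n_mutants + 1)]
    raw_genomes: dict = {}
    entries: list = []
    for i, mutant_id in enumerate(ems_ids, start=1):
        line_rng = np.random.default_rng(config.seed + i)
        genome, hits = mutagenize_ems(reference, config.background_density, line_rng)
        raw_genomes[mutant_id] = genome
        entries.extend(
            TruthEntry(mutant_id, cid, pos, ref, alt, CLASS_BACKGROUND)
            for cid, pos, ref, alt in hits
        )

    causal_hits = plant_causal(raw_genomes, causal, master)
    causal_keys = {
        (mutant_id, cid, pos) for mutant_id, (cid, pos, _, _) in causal_hits.items()
    }
    # a background hit can coincide with the planted site; keep the causal row
    entries = [
        e for e in entries
        if (e.mutant_id, e.contig_id, e.position) not in causal_keys
    ]
    entries.extend(
        TruthEntry(mutant_id, cid, pos, ref, alt, CLASS_CAUSAL)
        for mutant_id, (cid, pos, ref, alt) in causal_hits.items()
    )

    contaminant_id = None
    contaminant_ids: set = set()
    if config.contaminant:
        contaminant_id = f"mut{config.n_mutants + 1:02d}"
        cont_rng = np.random.default_rng(config.seed + config.n_mutants + 1)
        genome, hits = mutagenize_natural(reference, config.contaminant_density, cont_rng)
        raw_genomes[contaminant_id] = genome
        entries.extend(
            TruthEntry(contaminant_id, cid, pos, ref, alt, CLASS_NATURAL)
            for cid, pos, ref, alt in hits
        )
        contaminant_ids = {contaminant_id}

    wildtype_genome = None
    artifact_ids: set = set()
    if config.artifact_contig:
        wildtype_arrays = _as_arrays(reference)
        candidates = [
            c for c in reference if c.id != causal_id and c.length >= 2000
        ]
        if not candidates:
            raise ConfigError("no contig ≥ 2 kb available for the artifact scenario")
        artifact = candidates[int(master.integers(len(candidates)))]
        artifact_ids = {artifact.id}
        half = artifact.length // 2
        n_div = max(1, int(round(config.artifact_divergence * (artifact.length - half))))
        div_pos = master.choice(
            np.arange(half, artifact.length), size=n_div, replace=False
        )
        picks = master.integers(0, 3, size=n_div)
        for genome in [wildtype_arrays] + [raw_genomes[m] for m in raw_genomes]:
            arr = genome[artifact.id]
            for i, k in zip(div_pos.tolist(), picks.tolist()):
                ref = chr(arr[i]).upper()
                if ref not in _NON_REF:  # N never occurs here, lowercase does
                    continue
                arr[i] = ord(_NON_REF[ref][k])
        wildtype_genome = {
            cid: arr.tobytes().decode("ascii") for cid, arr in wildtype_arrays.items()
        }

    genomes = {
        line: {cid: arr.tobytes().decode("ascii") for cid, arr in g.items()}
        for line, g in raw_genomes.items()
    }
    entries.sort(key=lambda e: (e.mutant_id, e.contig_id, e.position))
    truth = TruthTable(causal_id, entries, contaminant_ids, artifact_ids)
    return Experiment(
        config, reference, ems_ids, contaminant_id, genomes, wildtype_genome, truth
    )


def simulate_experiment(config: SimulationConfig, out_dir) -> Path:
    """Simulate and write a complete experiment directory.

    Layout: reference.fasta, one <line>.mpileup per line, wildtype.mpileup
    when the wild-type self-mapping is enabled (always on for the artifact
    scenario), truth.tsv, manifest.yaml. Rerunning with the same config
    produces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    exp = simulate(config)

    write_fasta(exp.reference, out / "reference.fasta")
    files = {"reference": "reference.fasta", "pileups": {}}
    for line_id in exp.line_ids:
        name = f"{line_id}.mpileup"
        write_mpileup(exp.pileup_columns(line_id), out / name)
        files["pileups"][line_id] = name
    if config.wildtype_pileup or config.artifact_contig:
        write_mpileup(exp.pileup_columns(WILDTYPE_ID), out / "wildtype.mpileup")
        files["wildtype_pileup"] = "wildtype.mpileup"

    write_truth_tsv(exp.truth, out / "truth.tsv")
    files["truth"] = "truth.tsv"
    manifest = {"config": asdict(config), "files": files}
    with open(out / "manifest.yaml", "w") as handle:
        yaml.safe_dump(manifest, handle, sort_keys=True)
    return out


# ---------------------------------------------------------------------------
# Truth table I/O and truth-derived call sets


def write_truth_tsv(truth: TruthTable, path) -> None:
    with open(path, "w") as handle:
        handle.write(f"# causal_contig={truth.causal_contig_id}\n")
        handle.write(f"# contaminants={','.join(sorted(truth.contaminant_ids))}\n")
        handle.write(f"# artifact_contigs={','.join(sorted(truth.artifact_contig_ids))}\n")
        frame = pd.DataFrame(
            truth.entries,
            columns=["mutant_id", "contig", "position", "ref", "alt", "class"],
        )
        frame.to_csv(handle, sep="\t", index=False)


def read_truth_tsv(path) -> TruthTable:
    meta = {}
    with open(path) as handle:
        pos = handle.tell()
        while True:
            line = handle.readline()
            if not line.startswith("# "):
                handle.seek(pos)
                break
            key, _, value = line[2:].rstrip("\n").partition("=")
            meta[key] = value
            pos = handle.tell()
        frame = pd.read_csv(handle, sep="\t")
    entries = [
        TruthEntry(str(r.mutant_id), str(r.contig), int(r.position),
                   str(r.ref), str(r.alt), str(getattr(r, "_5")))
        for r in frame.itertuples(index=False)
    ]
    def _split(s):
        return set(s.split(",")) if s else set()
    return TruthTable(
        meta.get("causal_contig", ""),
        entries,
        _split(meta.get("contaminants", "")),
        _split(meta.get("artifact_contigs", "")),
    )


def ideal_callsets(exp: Experiment, mutant_ids: Optional[Sequence[str]] = None) -> list:
    """Call sets an error-free caller recovers when every position is callable.

    Useful for exercising integration and ranking without synthesizing read
    columns; caller-vs-truth exactness is verified separately on real columns.
    """
    if mutant_ids is None:
        mutant_ids = exp.ems_mutant_ids
    depth = int(exp.config.coverage_lambda)
    callable_bases = sum(c.unmasked_bases for c in exp.reference)
    by_mutant = exp.truth.by_mutant()
    out = []
    for mutant_id in mutant_ids:
        calls = [
            SnvCall(mutant_id, e.contig_id, e.position, e.ref.upper(), e.alt,
                    1.0, depth, is_canonical(e.ref.upper(), e.alt))
            for e in by_mutant.get(mutant_id, [])
        ]
        calls.sort(key=lambda s: (s.contig_id, s.position))
        out.append(MutantCallSet(mutant_id, calls, callable_bases))
    return out
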