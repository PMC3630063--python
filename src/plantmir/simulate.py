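"""Seeded, ground-truth-annotated simulation of a plant small-RNA experiment.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without any external download:

* a genome carrying planted hairpin precursors (perfect inverted repeats,
  stem >= 36 bp, loop of ``loop_length`` nt) whose mature/star duplexes obey
  the canonical Dicer geometry: the star pairs mature positions 1..L-2 and
  both strands carry 2-nt 3' overhangs;
* two small-RNA libraries (control, drought) of adapter-bearing reads whose
  per-miRNA counts are negative-binomial around configured means, with
  drought means scaled by planted fold-changes, a configurable fraction of
  structural-RNA contaminant reads, and a pinch of junk (short or
  low-quality reads) to exercise cleaning;
* a transcriptome with exact-complement miRNA target sites;
* a degradome (PARE) library whose 5' ends concentrate on the transcript
  nucleotide paired to miRNA position 10, over a uniform background.

Identical config + seed gives byte-identical outputs.  Files use the DNA
alphabet; the in-memory truth uses RNA.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .seqtools import random_rna, read_fasta, revcomp, to_dna, to_rna

__all__ = [
    "SimulationConfig",
    "PlantedMiRNA",
    "TargetSite",
    "GroundTruth",
    "build_genome_with_hairpins",
    "simulate_small_rna_libraries",
    "simulate_transcriptome",
    "simulate_degradome_library",
    "simulate_count_table",
    "write_fixture_bundle",
]

DEFAULT_ADAPTER = "UCGUAUGCCGUCUUCUGCUUG"  # classic Illumina small-RNA 3' adapter


@dataclass
class SimulationConfig:
    """Knobs of the simulated study.

    Defaults describe the study conditions exercised throughout the test
    suite: 20 planted miRNAs on a 2 x 60-kb genome, 30 000 reads per library,
    negative-binomial dispersion 0.05, 10% structural-RNA contamination and a
    degradome in which 70% of 5' ends sit exactly on true cleavage sites.
    """

    seed: int = 1
    n_scaffolds: int = 2
    scaffold_length: int = 60_000
    n_hairpins: int = 20
    stem_length: int = 30
    loop_length: int = 8
    mature_length: int = 21
    n_transcripts: int = 20
    read_depth_per_library: int = 30_000
    adapter: str = DEFAULT_ADAPTER
    de_fold_changes: list[tuple[int, float]] = field(
        default_factory=lambda: [(0, 4.0), (1, 4.0), (2, 4.0), (3, 0.25), (4, 0.25)]
    )
    nb_dispersion: float = 0.05
    contaminant_fraction: float = 0.1
    degradome_signal_fraction: float = 0.7
    degradome_depth: int = 10_000
    junk_fraction: float = 0.03

    def __post_init__(self):
        self.adapter = to_rna(self.adapter)
        if self.stem_length < self.mature_length:
            raise ValueError("stem_length must be >= mature_length")
        if len(self.adapter) < 8:
            raise ValueError("adapter must be at least 8 nt")
        if not 0.0 <= self.contaminant_fraction <= 1.0:
            raise ValueError("contaminant_fraction must be in [0, 1]")
        if not 0.0 <= self.degradome_signal_fraction <= 1.0:
            raise ValueError("degradome_signal_fraction must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


@dataclass
class PlantedMiRNA:
    name: str
    mature: str
    star: str
    scaffold: str
    start: int  # 1-based inclusive, precursor span
    end: int
    strand: str
    arm: str  # "5'" or "3'"
    mature_offset: int  # 0-based offset of the mature within the precursor
    precursor: str


@dataclass
class TargetSite:
    mirna: str
    transcript_id: str
    site_start: int  # 1-based inclusive on the transcript sense strand
    site_end: int
    cleavage_pos: int  # transcript nucleotide paired to miRNA position 10


@dataclass
class GroundTruth:
    mirnas: list[PlantedMiRNA] = field(default_factory=list)
    expected_counts: dict[str, dict[str, float]] = field(default_factory=dict)
    target_sites: list[TargetSite] = field(default_factory=list)
    contaminants: list[dict] = field(default_factory=list)
    sirna_pairs: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        return cls(
            mirnas=[PlantedMiRNA(**m) for m in raw["mirnas"]],
            expected_counts=raw["expected_counts"],
            target_sites=[TargetSite(**t) for t in raw["target_sites"]],
            contaminants=raw["contaminants"],
            sirna_pairs=raw["sirna_pairs"],
        )


def _make_precursor(rng: np.random.Generator, cfg: SimulationConfig, arm: str):
    """Perfect inverted-repeat precursor with the duplex planted on one arm.

    Returns (precursor RNA, mature, star, mature_offset0).
    """
    lm = cfg.mature_length
    s_min = max(cfg.stem_length, lm + 6, (80 - cfg.loop_length + 1) // 2)
    s = int(rng.integers(s_min, s_min + 25))
    if arm == "5'":
        a = 3  # 1-based start of the mature on its arm's precursor coords
        # arm5 0-based positions paired to interior mature positions 4..16
        window = range(5, 18)
    else:
        a = s + cfg.loop_length + 3
        window = range(s - 18, s - 5)
    b = a + lm - 1
    # require wobble-capable (G/U) bases opposite the mature so the stem can
    # be imperfect without unpairing the duplex
    while True:
        arm5 = random_rna(rng, s)
        wobble_ok = [i for i in window if arm5[i] in "GU"]
        if len(wobble_ok) >= 3:
            break
    loop = random_rna(rng, cfg.loop_length)
    arm3 = list(revcomp(arm5))
    n = 2 * s + cfg.loop_length
    # plant G:U wobbles opposite the mature: still paired under the folding
    # model, but the precursor is no longer a palindrome, so the mature and
    # star map to one strand only (as real imperfect hairpins do)
    for i in rng.choice(wobble_ok, size=3, replace=False):
        p = n + 1 - (i + 1)  # 1-based partner of arm5 position i+1
        arm3[p - (s + cfg.loop_length) - 1] = "U" if arm5[i] == "G" else "G"
    pre = arm5 + loop + "".join(arm3)
    mature = pre[a - 1 : b]
    # perfect stem: partner(p) = n + 1 - p; star pairs mature 1..L-2 with
    # 2-nt 3' overhangs on both strands
    star_lo = n + 1 - (b - 2)
    star_hi = n + 1 - a + 2
    star = pre[star_lo - 1 : star_hi]
    return pre, mature, star, a - 1


def build_genome_with_hairpins(config: SimulationConfig):
    """Random genome with planted hairpin precursors and contaminant loci.

    Returns (genome FASTA text, GroundTruth, GFF3 text).  Coordinates are
    1-based inclusive with explicit strand, so the precursor length LP always
    equals end - start + 1.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 0xA11CE])
    scaffolds = {
        f"scaffold_{i + 1}": list(random_rna(rng, cfg.scaffold_length))
        for i in range(cfg.n_scaffolds)
    }
    names = list(scaffolds)
    truth = GroundTruth()

    per_scaffold = -(-cfg.n_hairpins // cfg.n_scaffolds)
    spacing = cfg.scaffold_length // (per_scaffold + 1)
    if spacing < 300 + 2 * 80:
        raise ValueError(
            "scaffolds too short to host the requested hairpins; "
            "increase scaffold_length or reduce n_hairpins"
        )
    gff_lines = ["##gff-version 3"]
    for k in range(cfg.n_hairpins):
        arm = "5'" if k % 2 == 0 else "3'"
        strand = "+" if k % 4 < 2 else "-"
        pre, mature, star, moff = _make_precursor(rng, cfg, arm)
        sc = names[k % cfg.n_scaffolds]
        slot = k // cfg.n_scaffolds
        start = (slot + 1) * spacing + int(rng.integers(0, 40))
        end = start + len(pre) - 1
        seq = scaffolds[sc]
        planted = pre if strand == "+" else revcomp(pre)
        seq[start - 1 : end] = list(planted)
        truth.mirnas.append(
            PlantedMiRNA(
                name=f"sim-miR{k + 1}",
                mature=mature,
                star=star,
                scaffold=sc,
                start=start,
                end=end,
                strand=strand,
                arm=arm,
                mature_offset=moff,
                precursor=pre,
            )
        )

    # structural-RNA contaminant loci: annotated intervals of plain genome
    n_cont = max(2, cfg.n_hairpins // 4)
    for k in range(n_cont):
        kind = "rRNA" if k % 2 == 0 else "tRNA"
        length = 120 if kind == "rRNA" else 75
        sc = names[k % cfg.n_scaffolds]
        start = int(rng.integers(200, cfg.scaffold_length // (per_scaffold + 1) - 300))
        # offset into the gap before the first hairpin slot
        end = start + length - 1
        truth.contaminants.append(
            {"scaffold": sc, "start": start, "end": end, "strand": "+", "type": kind}
        )
        gff_lines.append(
            f"{sc}\tplantmir_sim\t{kind}\t{start}\t{end}\t.\t+\t.\tID={kind}_{k + 1}"
        )

    # two siRNA-like duplex pairs (22-24 nt, 2-nt 3' overhangs on both ends)
    for k in range(2):
        sc = names[-1]
        length = int(rng.integers(22, 25))
        s1 = cfg.scaffold_length - 2000 - k * 400
        e1 = s1 + length - 1
        guide = "".join(scaffolds[sc][s1 - 1 : e1])
        passenger = revcomp("".join(scaffolds[sc][s1 - 3 : e1 - 2]))
        truth.sirna_pairs.append(
            {
                "scaffold": sc,
                "start": s1,
                "end": e1,
                "length": length,
                "guide": guide,
                "passenger": passenger,
            }
        )

    # expected per-library counts, scaled so the control library's signal
    # portion matches the configured read depth
    base = np.exp(rng.uniform(np.log(50), np.log(500), size=cfg.n_hairpins))
    signal_target = cfg.read_depth_per_library * (
        1.0 - cfg.contaminant_fraction - cfg.junk_fraction
    )
    base *= signal_target / (base.sum() * 1.05)
    fold = {i: fc for i, fc in cfg.de_fold_changes}
    for k, mir in enumerate(truth.mirnas):
        fc = fold.get(k, 1.0)
        mu = float(base[k])
        truth.expected_counts[mir.name] = {
            "control": mu,
            "drought": mu * fc,
            "star_control": max(5.0, 0.05 * mu),
            "star_drought": max(5.0, 0.05 * mu) * fc,
        }

    fasta = []
    for sc in names:
        fasta.append(f">{sc}")
        s = to_dna("".join(scaffolds[sc]))
        fasta.extend(s[i : i + 70] for i in range(0, len(s), 70))
    return "\n".join(fasta) + "\n", truth, "\n".join(gff_lines) + "\n"


def _fastq_record(name: str, seq_rna: str, qual: str | None = None) -> str:
    seq = to_dna(seq_rna)
    if qual is None:
        qual = "I" * len(seq)
    return f"@{name}\n{seq}\n+\n{qual}\n"


def _nb_counts(rng, means: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.asarray(means, dtype=float) / shape)
    return rng.poisson(lam)


def simulate_small_rna_libraries(genome_fasta: str, truth: GroundTruth, config: SimulationConfig):
    """Two small-RNA FASTQ texts (control, drought).

    Reads are mature/star sequences with the 3' adapter appended; counts are
    negative-binomial around the truth's expected means; contaminant reads
    are substrings (18-30 nt) of the annotated structural loci; a small junk
    fraction (short inserts, low quality) exercises the cleaning stage.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 0x5EED5])
    scaffolds = read_fasta(genome_fasta)

    libs = {"control": [], "drought": []}
    for lib in ("control", "drought"):
        out = libs[lib]
        names, means = [], []
        for mir in truth.mirnas:
            ec = truth.expected_counts[mir.name]
            names.append((mir.name, mir.mature))
            means.append(ec[lib])
            names.append((mir.name + "*", mir.star))
            means.append(ec[f"star_{lib}"])
        counts = _nb_counts(rng, np.array(means), cfg.nb_dispersion)
        idx = 0
        for (nm, seq), c in zip(names, counts):
            for r in range(int(c)):
                out.append(_fastq_record(f"{lib}_{nm}_{idx}", seq + cfg.adapter))
                idx += 1
        # siRNA duplex reads
        for pair in truth.sirna_pairs:
            for strand_name in ("guide", "passenger"):
                for r in range(30):
                    out.append(
                        _fastq_record(
                            f"{lib}_sirna_{pair['start']}_{strand_name}_{r}",
                            pair[strand_name] + cfg.adapter,
                        )
                    )
                    idx += 1
        n_sig = sum(int(c) for c in counts)
        n_cont = int(n_sig * cfg.contaminant_fraction / max(1e-9, 1 - cfg.contaminant_fraction))
        for r in range(n_cont):
            loc = truth.contaminants[int(rng.integers(0, len(truth.contaminants)))]
            length = int(rng.integers(18, 31))
            lo = int(rng.integers(loc["start"], loc["end"] - length + 2))
            seq = scaffolds[loc["scaffold"]][lo - 1 : lo + length - 1]
            out.append(_fastq_record(f"{lib}_cont_{r}", seq + cfg.adapter))
        n_junk = int(n_sig * cfg.junk_fraction)
        for r in range(n_junk):
            if r % 3 == 0:
                seq = random_rna(rng, int(rng.integers(8, 17)))  # too-short insert
                out.append(_fastq_record(f"{lib}_junk_{r}", seq + cfg.adapter))
            else:
                seq = random_rna(rng, 21)
                qual = "#" * (len(seq) + len(cfg.adapter))  # low quality
                out.append(_fastq_record(f"{lib}_junk_{r}", seq + cfg.adapter, qual))
    return "".join(libs["control"]), "".join(libs["drought"])


def simulate_transcriptome(truth: GroundTruth, config: SimulationConfig) -> str:
    """Transcriptome FASTA with one exact-complement target site per miRNA.

    Appends the planted sites to ``truth.target_sites``; the true cleavage
    position is the transcript nucleotide paired to miRNA position 10
    (site_end - 9 for an ungapped site).
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 0x7A46])
    records = []
    truth.target_sites = []
    for t in range(cfg.n_transcripts):
        tid = f"TR{t + 1:04d}"
        length = int(rng.integers(800, 1200))
        seq = list(random_rna(rng, length))
        if t < len(truth.mirnas):
            mir = truth.mirnas[t]
            site = revcomp(mir.mature)
            lo = int(rng.integers(100, length - len(site) - 100))  # 0-based
            seq[lo : lo + len(site)] = list(site)
            site_start = lo + 1
            site_end = lo + len(site)
            truth.target_sites.append(
                TargetSite(
                    mirna=mir.name,
                    transcript_id=tid,
                    site_start=site_start,
                    site_end=site_end,
                    cleavage_pos=site_end - 9,
                )
            )
        records.append((tid, "".join(seq)))
    out = []
    for tid, seq in records:
        out.append(f">{tid}")
        s = to_dna(seq)
        out.extend(s[i : i + 70] for i in range(0, len(s), 70))
    return "\n".join(out) + "\n"


def simulate_degradome_library(
    transcripts_fasta: str, truth: GroundTruth, config: SimulationConfig
) -> str:
    """Degradome FASTQ: 5' ends at true cleavage sites over uniform background.

    ``degradome_signal_fraction`` of reads start exactly at a true cleavage
    position; the rest start uniformly.  Reads are 20-21 nt of transcript
    sense strand (adapters already removed, as a PARE pipeline sees them).
    Sites within 20 nt of a transcript 3' end are skipped with a warning.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 0xDE64])
    tx = read_fasta(transcripts_fasta)
    usable = []
    for site in truth.target_sites:
        seq = tx[site.transcript_id]
        if site.cleavage_pos > len(seq) - 20:
            warnings.warn(
                f"cleavage site {site.transcript_id}:{site.cleavage_pos} is within "
                "20 nt of the transcript 3' end; skipped"
            )
            continue
        usable.append(site)
    tids = list(tx)
    reads = []
    for r in range(cfg.degradome_depth):
        if usable and rng.random() < cfg.degradome_signal_fraction:
            site = usable[int(rng.integers(0, len(usable)))]
            seq = tx[site.transcript_id]
            length = int(rng.integers(20, 22))
            frag = seq[site.cleavage_pos - 1 : site.cleavage_pos - 1 + length]
        else:
            tid = tids[int(rng.integers(0, len(tids)))]
            seq = tx[tid]
            length = int(rng.integers(20, 22))
            lo = int(rng.integers(0, len(seq) - length + 1))
            frag = seq[lo : lo + length]
        reads.append(_fastq_record(f"deg_{r}", frag))
    return "".join(reads)


def simulate_count_table(
    n_de: int = 10,
    n_null: int = 40,
    fold: float = 4.0,
    de_mean_range: tuple[float, float] = (50.0, 500.0),
    null_mean_range: tuple[float, float] = (5.0, 50.0),
    dispersion: float = 0.01,
    library_total: int = 1_000_000,
    seed: int = 1,
):
    """Counts-level differential-expression simulation.

    Returns a list of dicts (name, x, y, is_de) plus the two library totals.
    The first ``n_de`` miRNAs have drought means scaled by ``fold``; the rest
    are null.  Counts are negative-binomial with var = mu + dispersion*mu^2.
    Defaults model two single pooled libraries (technical, near-Poisson
    dispersion): DE miRNAs are moderately expressed (means >= 50); null
    novel miRNAs sit in the low-abundance band typical of such catalogs.
    """
    rng = np.random.default_rng([seed, 0xC0DE])
    rows = []
    means = np.concatenate(
        [
            np.exp(rng.uniform(np.log(de_mean_range[0]), np.log(de_mean_range[1]), n_de)),
            np.exp(rng.uniform(np.log(null_mean_range[0]), np.log(null_mean_range[1]), n_null)),
        ]
    )
    x = _nb_counts(rng, means, dispersion)
    mu_y = means.copy()
    mu_y[:n_de] *= fold
    y = _nb_counts(rng, mu_y, dispersion)
    for i in range(n_de + n_null):
        rows.append(
            {
                "name": f"mir{i + 1}",
                "x": int(x[i]),
                "y": int(y[i]),
                "is_de": i < n_de,
            }
        )
    return rows, library_total, library_total




def write_fixture_bundle(outdir, config: SimulationConfig | None = None) -> dict:
    """Generate every simulated input plus the packaged novel-miRNA catalog.

    Writes genome.fa, transcripts.fa, annotation.gff3, control.fastq,
    drought.fastq, degradome.fastq, truth.json and novel_mirna_catalog.tsv
    into ``outdir`` and returns a manifest dict listing the files.
    """
    cfg = config or SimulationConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome, truth, gff = build_genome_with_hairpins(cfg)
    control, drought = simulate_small_rna_libraries(genome, truth, cfg)
    transcripts = simulate_transcriptome(truth, cfg)
    degradome = simulate_degradome_library(transcripts, truth, cfg)
    catalog = resources.files("plantmir.data").joinpath("novel_mirna_catalog.tsv").read_text()
    files = {
        "genome.fa": genome,
        "transcripts.fa": transcripts,
        "annotation.gff3": gff,
        "control.fastq": control,
        "drought.fastq": drought,
        "degradome.fastq": degradome,
        "truth.json": truth.to_json(),
        "novel_mirna_catalog.tsv": catalog,
    }
    for name, text in files.items():
        (out / name).write_text(text)
    return {"outdir": str(out), "files": sorted(files), "seed": cfg.seed}
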