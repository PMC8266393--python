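"""Synthetic dual-genome spike-in experiments with known ground truth.

The generator emulates the statistical structure the quantification
pipeline assumes, at desk scale:

* a gene annotation on one synthetic chromosome, both strands, with
  TSS/PAS, TFIID-dependent vs coactivator-redundant (CR) class labels
  and planted TATA boxes;
* nascent RNA-seq count tables from a negative-binomial model with an
  8:1 experimental:spike cell-mix design (spike reads track sequencing
  depth while the experimental transcriptome shrinks under depletion);
* promoter-peaked MNase-fusion (ChEC-style) coverage with matched
  free-MNase controls, and Pol II-style TSS-to-PAS coverage with an
  optional 5' accumulation that shifts the traveling ratio;
* a :class:`TruthBundle` with the injected fold changes, bound
  promoters, summit positions and TR shifts for recovery tests.

Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .annotation import GeneModel, reverse_complement, write_genes_tsv
from .coverage import CoverageTrack
from .samples import SampleMeta, write_sample_sheet


class SimulationError(ValueError):
    """Invalid simulation configuration (sizing, fractions, replicates)."""


@dataclass(frozen=True)
class ClassEffect:
    """Distribution of the injected true log2 fold change for one gene class."""

    median_log2fc: float = 0.0
    sd: float = 0.0


@dataclass(frozen=True)
class PeakSpec:
    """Promoter peak shape for ChEC-style tracks.

    fold is the mean IP enrichment over the control within a 200 bp
    window at the summit; the pileup is a discretized Gaussian of width
    sigma. iaa_log2_change is the injected occupancy change at bound
    promoters after depletion (default ~1.7-fold decrease).
    """

    fold: float = 8.0
    sigma: float = 75.0
    bound_fraction: float = 0.6
    iaa_log2_change: float = -math.log2(1.7)
    background: float = 1.0


@dataclass(frozen=True)
class ElongationSpec:
    """5' accumulation injected into IAA Pol II tracks.

    Per gene, the IAA density is multiplied by
    ``1 + strength * exp(-d / decay_bp)`` at distance d downstream of the
    TSS, with ``strength = shift_coef * max(0, -log2fc)`` so the most
    depletion-dependent genes gain the strongest promoter-proximal
    polymerase accumulation. Independently, a random ``shift_fraction``
    of genes receives a fixed extra ``uniform_strength`` (useful for
    contrasting shifted vs unshifted gene sets under a null effect).
    kinase_gain_fold scales a kinase-style track uniformly in IAA.
    """

    shift_coef: float = 1.0
    decay_bp: float = 400.0
    kinase_gain_fold: float = 1.4
    uniform_strength: float = 0.0
    shift_fraction: float = 0.0


@dataclass
class SimulationConfig:
    """All knobs of the synthetic experiment; defaults are the study conditions."""

    n_genes: int = 2000
    chrom: str = "chrSimI"
    chrom_length: Optional[int] = None  # None -> sized automatically
    class_fractions: dict = field(default_factory=lambda: {"TFIID": 0.87, "CR": 0.13})
    effect_spec: dict = field(
        default_factory=lambda: {
            "TFIID": ClassEffect(median_log2fc=-2.0, sd=0.4),
            "CR": ClassEffect(median_log2fc=-math.log2(1.3), sd=0.25),
        }
    )
    tata_fraction_per_class: dict = field(
        default_factory=lambda: {"TFIID": 0.1, "CR": 0.6}
    )
    n_replicates: int = 3
    replicate_cv: float = 0.2
    spike_ratio: float = 0.125  # expected spike:experimental read ratio (8:1 mix)
    nb_dispersion: float = 0.05
    mean_expression: float = 200.0
    expression_sigma: float = 1.0
    base_depth: Optional[int] = None  # None -> 450 reads/gene
    peak_spec: PeakSpec = field(default_factory=PeakSpec)
    elongation_spec: ElongationSpec = field(default_factory=ElongationSpec)
    gene_length_range: tuple[int, int] = (500, 4000)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0:
            raise SimulationError("n_genes must be >= 0")
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise SimulationError("class_fractions must sum to 1")
        for name, f in list(self.class_fractions.items()) + list(
            self.tata_fraction_per_class.items()
        ):
            if not 0.0 <= f <= 1.0:
                raise SimulationError(f"fraction {name}={f} outside [0, 1]")
        if not 0.0 <= self.peak_spec.bound_fraction <= 1.0:
            raise SimulationError("bound_fraction outside [0, 1]")
        if self.replicate_cv < 0 or self.spike_ratio <= 0 or self.nb_dispersion < 0:
            raise SimulationError("replicate_cv/spike_ratio/nb_dispersion invalid")


@dataclass
class TruthBundle:
    """Ground truth of one simulated experiment, for recovery tests."""

    true_log2fc: Optional[pd.Series] = None
    true_bound: set = field(default_factory=set)
    true_summits: dict = field(default_factory=dict)
    true_tr_shift: Optional[pd.Series] = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_log2fc": None if self.true_log2fc is None else self.true_log2fc.to_dict(),
            "true_bound": sorted(self.true_bound),
            "true_summits": self.true_summits,
            "true_tr_shift": None if self.true_tr_shift is None else self.true_tr_shift.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _plant_and_scrub_tata(
    seq: np.ndarray,
    genes: list[GeneModel],
    rng: np.random.Generator,
    scan_upstream: int = 200,
) -> None:
    """Plant a TATAWAW in TATA-flagged promoters; remove chance matches elsewhere."""
    import re

    motif_re = re.compile(b"TATA[AT]A[AT]")
    for g in genes:
        if g.strand == "+":
            lo, hi = max(g.tss - scan_upstream, 0), g.tss
        else:
            lo, hi = g.tss, g.tss + scan_upstream
        if hi - lo < 7:
            continue
        if not g.tata:
            # break any chance consensus so truth flags match a regex scan
            window = seq[lo:hi].tobytes()
            rc = g.strand == "-"
            probe = reverse_complement(window.decode()).encode() if rc else window
            while True:
                m = motif_re.search(probe)
                if m is None:
                    break
                mid = m.start() + 3  # central A of TATAWAW -> C kills the match
                gpos = (lo + mid) if not rc else (hi - 1 - mid)
                seq[gpos] = b"C" if not rc else b"G"
                window = seq[lo:hi].tobytes()
                probe = reverse_complement(window.decode()).encode() if rc else window
            continue
        w1, w2 = rng.choice([b"A", b"T"], size=2)
        motif = b"TATA" + w1 + b"A" + w2
        pos = int(rng.integers(0, hi - lo - len(motif) + 1))
        sense_window = bytearray(seq[lo:hi].tobytes())
        if g.strand == "+":
            sense_window[pos:pos + 7] = motif
            seq[lo:hi] = np.frombuffer(bytes(sense_window), dtype="S1")
        else:
            sense = bytearray(reverse_complement(seq[lo:hi].tobytes().decode()).encode())
            sense[pos:pos + 7] = motif
            back = reverse_complement(bytes(sense).decode()).encode()
            seq[lo:hi] = np.frombuffer(back, dtype="S1")


def simulate_annotation(cfg: SimulationConfig) -> tuple[list[GeneModel], dict[str, str]]:
    """Lay out non-overlapping genes on both strands and emit a genome.

    Returns (gene models with TSS/PAS/class/TATA set, {chrom: sequence}).
    TATA-flagged genes carry a planted TATAWAW in the −200..TSS sense-strand
    scan window; chance matches in non-flagged windows are scrubbed so the
    flags are exactly recoverable by a motif scan.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 11])
    classes = list(cfg.class_fractions)
    probs = np.array([cfg.class_fractions[c] for c in classes])

    genes: list[GeneModel] = []
    cursor = 1000
    lo_len, hi_len = cfg.gene_length_range
    for i in range(cfg.n_genes):
        length = int(np.clip(round(rng.lognormal(math.log(1400), 0.35)), lo_len, hi_len))
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = cursor, cursor + length
        cls = classes[int(rng.choice(len(classes), p=probs))]
        tata = bool(rng.random() < cfg.tata_fraction_per_class.get(cls, 0.0))
        if strand == "+":
            tss, pas, cds = start, end, start + 100
        else:
            tss, pas, cds = end, start, end - 100
        genes.append(
            GeneModel(
                gene_id=f"SIM{i + 1:05d}", chrom=cfg.chrom, strand=strand,
                start=start, end=end, cds_start=cds, tss=tss, pas=pas,
                biotype="verified", class_label=cls, tata=tata,
            )
        )
        cursor = end + int(rng.integers(700, 1100))

    needed = cursor + 1000
    if cfg.chrom_length is not None and cfg.chrom_length < needed:
        raise SimulationError(
            f"chrom_length {cfg.chrom_length} too small for {cfg.n_genes} genes "
            f"(needs >= {needed})"
        )
    chrom_len = cfg.chrom_length if cfg.chrom_length is not None else needed
    seq = _BASES[rng.integers(0, 4, size=chrom_len)]
    _plant_and_scrub_tata(seq, genes, rng)
    genome = {cfg.chrom: seq.tobytes().decode()}
    return genes, genome


def _depth_jitter(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return float(rng.lognormal(-0.5 * sigma * sigma, sigma))


def _draw_log2fc(
    cfg: SimulationConfig, genes: list[GeneModel], rng: np.random.Generator
) -> pd.Series:
    lfc = np.empty(len(genes))
    for i, g in enumerate(genes):
        eff = cfg.effect_spec.get(g.class_label, ClassEffect())
        lfc[i] = eff.median_log2fc + (rng.normal(0.0, eff.sd) if eff.sd > 0 else 0.0)
    return pd.Series(lfc, index=[g.gene_id for g in genes], name="true_log2fc")


def simulate_counts(
    cfg: SimulationConfig, genes: list[GeneModel]
) -> tuple[pd.DataFrame, list[SampleMeta], TruthBundle]:
    """Nascent RNA-seq count tables with spike totals and injected effects.

    Read allocation mimics the cell-mix design: the spike-in RNA mass is
    fixed relative to the *control* transcriptome, so when depletion
    shrinks the experimental transcriptome the spike fraction of a fixed
    sequencing depth grows. Spike reads are Binomial(depth, spike
    fraction), co-varying with depth; gene counts are negative binomial
    at dispersion ``nb_dispersion``. With ``replicate_cv == 0`` and
    ``nb_dispersion == 0`` the counts are deterministic rounded means.
    """
    cfg.validate()
    if cfg.n_replicates < 1:
        raise SimulationError("n_replicates must be >= 1")
    rng = np.random.default_rng([cfg.seed, 23])
    gene_ids = [g.gene_id for g in genes]
    if not genes:
        return (
            pd.DataFrame(index=pd.Index([], name="gene_id")),
            [],
            TruthBundle(true_log2fc=pd.Series(dtype=float)),
        )

    mu = rng.lognormal(math.log(cfg.mean_expression), cfg.expression_sigma, len(genes))
    lfc = _draw_log2fc(cfg, genes, rng)
    mass = {"DMSO": mu, "IAA": mu * np.power(2.0, lfc.to_numpy())}
    cer_mass = {c: float(m.sum()) for c, m in mass.items()}
    spike_mass = cfg.spike_ratio * cer_mass["DMSO"]
    base_depth = cfg.base_depth if cfg.base_depth is not None else 450 * len(genes)
    deterministic = cfg.replicate_cv == 0 and cfg.nb_dispersion == 0

    columns: dict[str, np.ndarray] = {}
    metas: list[SampleMeta] = []
    for cond in ("DMSO", "IAA"):
        f_spike = spike_mass / (spike_mass + cer_mass[cond])
        for rep in range(1, cfg.n_replicates + 1):
            depth = int(round(base_depth * _depth_jitter(rng, cfg.replicate_cv)))
            if deterministic:
                spike = int(round(depth * f_spike))
            else:
                spike = int(rng.binomial(depth, f_spike))
            exp_reads = depth - spike
            mu_counts = exp_reads * mass[cond] / cer_mass[cond]
            if deterministic:
                counts = np.round(mu_counts).astype(int)
            elif cfg.nb_dispersion > 0:
                n_nb = 1.0 / cfg.nb_dispersion
                counts = rng.negative_binomial(n_nb, n_nb / (n_nb + mu_counts))
            else:
                counts = rng.poisson(mu_counts)
            sid = f"rnaseq_{cond}_rep{rep}"
            columns[sid] = counts
            metas.append(
                SampleMeta(
                    sample_id=sid, assay="rnaseq", condition=cond, replicate=rep,
                    spike_reads=max(spike, 1), experimental_reads=int(counts.sum()),
                )
            )
    table = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    return table, metas, TruthBundle(true_log2fc=lfc)


def _add_gaussian_pileup(
    out: np.ndarray, center: int, sigma: float, mass: float, factor: float = 1.0
) -> None:
    """Add a discretized Gaussian pileup of total `mass`, truncated at 4 sigma."""
    lo = max(int(center - 4 * sigma), 0)
    hi = min(int(center + 4 * sigma) + 1, out.size)
    if hi <= lo:
        return
    x = np.arange(lo, hi)
    dens = np.exp(-0.5 * ((x - center) / sigma) ** 2)
    out[lo:hi] += factor * mass * dens / dens.sum()


def simulate_tracks(
    cfg: SimulationConfig,
    genes: list[GeneModel],
    kind: str = "promoter",
) -> tuple[dict[tuple[str, str, int], CoverageTrack], list[SampleMeta], TruthBundle]:
    """Raw coverage tracks for a ChEC-style or Pol II-style experiment.

    ``kind='promoter'`` plants unimodal fragment pileups at bound
    promoters over a uniform background, with the paired free-MNase
    control uniform; ``kind='polii'`` lays expression-scaled coverage
    from TSS to PAS with the configured 5' accumulation in IAA, plus a
    kinase-style track with a uniform IAA gain and a chromatin input.

    Returns ({(role, condition, replicate): raw CoverageTrack}, sample
    metadata, truth). Roles are ``ip``/``control`` for promoter tracks
    and ``ip``/``kinase``/``input`` for Pol II tracks.
    """
    cfg.validate()
    if kind not in ("promoter", "polii"):
        raise SimulationError(f"unknown track kind {kind!r}")
    if cfg.n_replicates < 1:
        raise SimulationError("n_replicates must be >= 1")
    rng = np.random.default_rng([cfg.seed, 31 if kind == "promoter" else 37])
    if genes:
        chrom_len = max(g.end for g in genes) + 1000
    else:
        chrom_len = cfg.chrom_length or 2000
    if cfg.chrom_length is not None:
        if cfg.chrom_length < chrom_len:
            raise SimulationError("chrom_length too small for the annotation")
        chrom_len = cfg.chrom_length

    truth = TruthBundle()
    intensity: dict[tuple[str, str], np.ndarray] = {}
    ps = cfg.peak_spec

    if kind == "promoter":
        bg = ps.background
        base = {"DMSO": np.full(chrom_len, bg), "IAA": np.full(chrom_len, bg)}
        frac_200 = math.erf(100.0 / (ps.sigma * math.sqrt(2.0))) if ps.sigma > 0 else 1.0
        mass = max(ps.fold - 1.0, 0.0) * bg * 200.0 / max(frac_200, 1e-9)
        # iaa_log2_change is defined on the 200 bp summit-window signal
        # (background included), matching what promoter occupancy measures;
        # solve for the factor applied to the peak mass itself.
        if ps.fold > 1.0:
            iaa_factor = max(
                (ps.fold * 2.0 ** ps.iaa_log2_change - 1.0) / (ps.fold - 1.0), 0.0
            )
        else:
            iaa_factor = 2.0 ** ps.iaa_log2_change
        for g in genes:
            if rng.random() >= ps.bound_fraction or mass <= 0:
                continue
            if g.strand == "+":
                summit = int(rng.integers(g.tss - 260, g.tss + 60))
            else:
                summit = int(rng.integers(g.tss - 60, g.tss + 260))
            truth.true_bound.add(g.gene_id)
            truth.true_summits[g.gene_id] = summit
            _add_gaussian_pileup(base["DMSO"], summit, ps.sigma, mass)
            _add_gaussian_pileup(base["IAA"], summit, ps.sigma, mass, factor=iaa_factor)
        intensity = {("ip", c): base[c] for c in ("DMSO", "IAA")}
        intensity[("control", "DMSO")] = np.full(chrom_len, bg)
        intensity[("control", "IAA")] = np.full(chrom_len, bg)
        roles = ("ip", "control")
        assay = "chec"
    else:
        mu = rng.lognormal(math.log(cfg.mean_expression), cfg.expression_sigma, len(genes))
        lfc = _draw_log2fc(cfg, genes, rng)
        truth.true_log2fc = lfc
        es = cfg.elongation_spec
        dens_d = np.full(chrom_len, 0.05)
        dens_i = np.full(chrom_len, 0.05)
        tr_shift = {}
        for g, m in zip(genes, mu):
            lo, hi = g.transcribed_interval()
            body = m / 100.0
            dens_d[lo:hi] += body
            fc = 2.0 ** lfc[g.gene_id]
            strength = es.shift_coef * max(0.0, -float(lfc[g.gene_id]))
            if es.shift_fraction > 0 and rng.random() < es.shift_fraction:
                strength += es.uniform_strength
            if g.strand == "+":
                dist = np.arange(lo, hi) - g.tss
            else:
                dist = (g.tss - 1) - np.arange(lo, hi)
            gain = 1.0 + strength * np.exp(-dist / es.decay_bp)
            dens_i[lo:hi] += body * fc * gain
            # expected log2 TR change from the injected profile
            g5 = 1.0 + strength * np.mean(np.exp(-np.arange(100) / es.decay_bp))
            L = hi - lo
            g3 = 1.0 + strength * np.mean(np.exp(-(L - 100 + np.arange(100)) / es.decay_bp))
            tr_shift[g.gene_id] = math.log2(g5 / g3)
        truth.true_tr_shift = pd.Series(tr_shift, name="true_tr_shift")
        intensity[("ip", "DMSO")] = dens_d
        intensity[("ip", "IAA")] = dens_i
        kg = es.kinase_gain_fold
        intensity[("kinase", "DMSO")] = dens_d.copy()
        intensity[("kinase", "IAA")] = dens_i * kg
        intensity[("input", "DMSO")] = np.full(chrom_len, 0.5)
        intensity[("input", "IAA")] = np.full(chrom_len, 0.5)
        roles = ("ip", "kinase", "input")
        assay = "chip"

    spike_expected = {
        role: cfg.spike_ratio * float(intensity[(role, "DMSO")].sum()) for role in roles
    }
    tracks: dict[tuple[str, str, int], CoverageTrack] = {}
    metas: list[SampleMeta] = []
    for cond in ("DMSO", "IAA"):
        for rep in range(1, cfg.n_replicates + 1):
            jit = _depth_jitter(rng, cfg.replicate_cv)
            for role in roles:
                lam = intensity[(role, cond)] * jit
                arr = rng.poisson(lam).astype(float)
                track = CoverageTrack.from_dense({cfg.chrom: arr})
                sid = f"{kind}_{role}_{cond}_rep{rep}"
                spike = max(int(rng.poisson(jit * spike_expected[role])), 1)
                link = f"{kind}_input_{cond}_rep{rep}" if (assay == "chip" and role != "input") else None
                metas.append(
                    SampleMeta(
                        sample_id=sid, assay=assay, condition=cond, replicate=rep,
                        spike_reads=spike, experimental_reads=int(arr.sum()),
                        input_link=link,
                    )
                )
                tracks[(role, cond, rep)] = track
    return tracks, metas, truth


def write_genome_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def emit_bundle(
    cfg: SimulationConfig,
    outdir: str | Path,
    kinds: tuple[str, ...] = ("counts",),
) -> None:
    """Write a complete synthetic dataset (annotation + requested assays)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genes, genome = simulate_annotation(cfg)
    write_genes_tsv(genes, out / "genes.tsv")
    write_genome_fasta(genome, out / "genome.fa")
    all_metas: list[SampleMeta] = []
    if "counts" in kinds:
        counts, metas, truth = simulate_counts(cfg, genes)
        counts.to_csv(out / "counts.tsv", sep="\t")
        truth.to_json(out / "truth_counts.json")
        all_metas += metas
    for kind in ("promoter", "polii"):
        if kind not in kinds:
            continue
        tracks, metas, truth = simulate_tracks(cfg, genes, kind=kind)
        for (role, cond, rep), track in sorted(tracks.items()):
            track.to_bedgraph(out / f"{kind}_{role}_{cond}_rep{rep}.bedgraph")
        truth.to_json(out / f"truth_{kind}.json")
        all_metas += metas
    write_sample_sheet(all_metas, out / "samples.tsv")
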