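"""Synthetic paired metagenome/metabolome/phenotype studies with planted truth.

Emulates the statistical structure a sterol-enzyme discovery analysis
assumes, so every pipeline stage can be verified against a known ground
truth: a clade of "encoder" species shares a divergent planted enzyme family
(target pairwise amino-acid identities to a common root spanning roughly
50-95%); species occur in samples with configurable prevalence and log-normal
relative abundances, with the encoder clade calibrated to a small mean share
of the community (1.4% by default); a stool metabolite (coprostanol) is
detected noisily when an encoder species is present, with lower stool
cholesterol and higher cholestenone in encoder samples; and serum total
cholesterol is shifted by a configurable effect (-0.15 mmol/L by default) in
encoders, on top of age/sex/antibiotic/statin covariate effects.

The planted family diverges along a *shared* path: one site-order permutation
and one replacement residue per site are drawn for the family, and a variant
with target identity t mutates the first round((1-t)*L) sites in that order.
Two variants therefore differ only at sites mutated in exactly one of them,
which keeps every within-family identity at least 1 - (hi - lo) and
guarantees the family forms a single cluster at the >50% identity threshold.
A small fraction of divergence events are rendered as single-residue indels
instead of substitutions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .seqcluster import SequenceRecord

__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "simulate_enzyme_family",
    "simulate_community_samples",
    "simulate_metabolome",
    "simulate_host_phenotypes",
    "simulate_study",
    "simulate_encoder_converter",
    "write_study_bundle",
    "read_study_bundle",
]

AA = "ACDEFGHIKLMNPQRSTVWY"

# one codon per amino acid is enough for back-translation of synthetic genes
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCG", "Q": "CAG", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


@dataclass
class SimulationConfig:
    """Parameters of a synthetic paired study; defaults are the study conditions.

    Probabilities must lie in [0, 1]; the planted identity range must satisfy
    low <= high; the encoder clade cannot exceed the species count.
    """

    n_samples: int = 200
    n_species: int = 30
    genes_per_species: int = 6
    encoder_species: int = 4
    planted_identity_range: tuple[float, float] = (0.55, 0.90)
    species_prevalence: float = 0.6
    encoder_prevalence: float = 0.14
    encoder_rel_abundance: float = 0.014
    abundance_lognormal_mu_sigma: tuple[float, float] = (0.0, 1.0)
    sequencing_depth: float = 2e5
    detect_prob_delta: float = 0.95
    background_fp_epsilon: float = 0.02
    cholesterol_reduction_range: tuple[float, float] = (0.25, 0.45)
    cholestenone_fold_range: tuple[float, float] = (3.3, 5.4)
    lipid_effect_beta: float = -0.15
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.005, "sex": 0.1, "antibiotics": 0.0,
                                 "statin": -1.2}
    )
    noise_sd: float = 0.9
    baseline_tc: float = 5.2
    samples_per_participant: int = 1
    protein_length: int = 260
    indel_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("species_prevalence", "encoder_prevalence", "encoder_rel_abundance",
                     "detect_prob_delta", "background_fp_epsilon", "indel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.planted_identity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("planted_identity_range must satisfy 0 <= low <= high <= 1")
        for name in ("n_samples", "n_species", "genes_per_species", "encoder_species",
                     "samples_per_participant", "protein_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.encoder_species > self.n_species:
            raise ValueError("encoder_species cannot exceed n_species")
        if self.sequencing_depth < 0:
            raise ValueError("sequencing_depth must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SyntheticStudy:
    """A complete synthetic study with planted ground truth."""

    config: SimulationConfig
    proteins: list[SequenceRecord]
    genes: list[SequenceRecord]
    truth: pd.DataFrame               # species, encoder flag, planted gene id
    species_presence: pd.DataFrame    # species x samples booleans
    counts: pd.DataFrame              # genes x samples integer read counts
    gene_lengths: pd.Series           # nucleotide lengths per gene
    metabolites: pd.DataFrame         # per-sample calls + relative abundances
    phenotypes: pd.DataFrame          # per-participant covariates + lipids
    isolate_proteins: list[SequenceRecord]
    enzyme_queries: list[SequenceRecord]
    seed_used: int


class _DivergencePath:
    """Shared mutation path for one protein family (see module docstring)."""

    def __init__(self, root: str, rng: np.random.Generator):
        if not root:
            raise ValueError("root protein must be non-empty")
        self.root = root
        self.site_order = rng.permutation(len(root))
        self.replacement = [
            rng.choice([a for a in AA if a != res]) for res in root
        ]

    def variant(self, target_identity: float, rng: np.random.Generator,
                indel_fraction: float) -> str:
        length = len(self.root)
        n_events = int(round((1.0 - target_identity) * length))
        sites = set(self.site_order[:n_events])
        n_indels = int(rng.binomial(n_events, indel_fraction)) if n_events else 0
        indel_sites = set(self.site_order[max(0, n_events - n_indels):n_events])
        out: list[str] = []
        for i, res in enumerate(self.root):
            if i in indel_sites:
                if rng.random() < 0.5:
                    continue  # deletion of the diverged site
                out.append(res)
                out.append(self.replacement[i])  # insertion next to it
            elif i in sites:
                out.append(self.replacement[i])
            else:
                out.append(res)
        return "".join(out)


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA), size=length))


def simulate_enzyme_family(
    root_protein: str,
    n_variants: int,
    identity_range: tuple[float, float],
    seed: int | np.random.Generator = 0,
    indel_fraction: float = 0.02,
) -> list[str]:
    """Plant a divergent enzyme family around a root protein.

    Target identities to the root are spaced evenly across ``identity_range``
    (low endpoint first); realized global-alignment identities stay within
    about +/-0.03 of the targets, and lengths are preserved up to the small
    indel fraction.
    """
    if not root_protein:
        raise ValueError("root protein must be non-empty")
    if n_variants < 0:
        raise ValueError("n_variants must be non-negative")
    lo, hi = identity_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("identity_range must satisfy 0 <= low <= high <= 1")
    if n_variants == 0:
        return []
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    path = _DivergencePath(root_protein, rng)
    targets = np.linspace(lo, hi, n_variants)
    return [path.variant(t, rng, indel_fraction) for t in targets]


def _back_translate(protein: str) -> str:
    return "".join(_CODON[a] for a in protein) + "TAA"


def _prevalence_vector(config: SimulationConfig, encoder_flags: np.ndarray) -> np.ndarray:
    prev = np.asarray(config.species_prevalence, dtype=float)
    if prev.ndim == 0:
        prev = np.full(config.n_species, float(prev))
    if prev.shape != (config.n_species,):
        raise ValueError("species_prevalence must be scalar or one value per species")
    prev = prev.copy()
    prev[encoder_flags] = config.encoder_prevalence
    return prev


def _encoder_scale(config: SimulationConfig, prevalence: np.ndarray,
                   encoder_flags: np.ndarray) -> float:
    # First-order calibration of the encoder clade's mean community share:
    # solve p = f*E_enc / (f*E_enc + E_bg) for the abundance scale factor f,
    # with E_* the prevalence-weighted expected number of present species.
    p = config.encoder_rel_abundance
    e_enc = prevalence[encoder_flags].sum()
    e_bg = prevalence[~encoder_flags].sum()
    if p <= 0 or e_enc == 0:
        return 1.0
    if p >= 1 or e_bg == 0:
        return 1.0
    return p * e_bg / (e_enc * (1.0 - p))


def simulate_community_samples(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SyntheticStudy:
    """Sequences, species presence, and gene-by-sample read counts.

    Species occur per sample as Bernoulli(prevalence); present species draw
    log-normal relative abundances (the encoder clade scaled to its
    configured mean share), renormalized within the sample; each gene's read
    count is Poisson with expectation depth * species share * gene length /
    species gene-length total. Metabolites and phenotypes are left empty;
    :func:`simulate_study` fills them.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    mu, sigma = config.abundance_lognormal_mu_sigma

    encoder_flags = np.zeros(config.n_species, dtype=bool)
    encoder_flags[: config.encoder_species] = True
    species_ids = [f"species_{i:03d}" for i in range(config.n_species)]

    root = random_protein(config.protein_length, rng)
    path = _DivergencePath(root, rng)
    lo, hi = config.planted_identity_range
    targets = np.linspace(lo, hi, config.encoder_species) if config.encoder_species else []

    proteins: list[SequenceRecord] = []
    genes: list[SequenceRecord] = []
    planted: dict[str, str] = {}
    gene_species: list[str] = []
    variant_idx = 0
    for s, sp in enumerate(species_ids):
        for g in range(config.genes_per_species):
            gid = f"{sp}_g{g:02d}"
            if encoder_flags[s] and g == 0:
                aa = path.variant(targets[variant_idx], rng, config.indel_fraction)
                variant_idx += 1
                planted[sp] = gid
            else:
                aa = random_protein(int(rng.integers(120, 400)), rng)
            proteins.append(SequenceRecord(gid, aa, source=sp))
            genes.append(SequenceRecord(gid, _back_translate(aa), source=sp))
            gene_species.append(sp)

    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]
    prevalence = _prevalence_vector(config, encoder_flags)
    scale = _encoder_scale(config, prevalence, encoder_flags)

    present = rng.random((config.n_species, config.n_samples)) < prevalence[:, None]
    raw = rng.lognormal(mu, sigma, size=present.shape) * present
    raw[encoder_flags] *= scale
    totals = raw.sum(axis=0)
    share = np.divide(raw, totals, out=np.zeros_like(raw), where=totals > 0)

    gene_lengths = pd.Series([g.length for g in genes], index=[g.id for g in genes])
    species_index = pd.Index(species_ids)
    sp_pos = species_index.get_indexer(gene_species)
    sp_len_total = gene_lengths.groupby(gene_species).sum().reindex(species_ids).to_numpy()
    gene_frac = gene_lengths.to_numpy() / sp_len_total[sp_pos]
    expected = config.sequencing_depth * share[sp_pos] * gene_frac[:, None]
    counts = rng.poisson(expected)

    truth = pd.DataFrame(
        {
            "species": species_ids,
            "encoder": encoder_flags,
            "planted_gene": [planted.get(sp, "") for sp in species_ids],
        }
    ).set_index("species")

    isolate = [SequenceRecord("isolate_root", root, source="isolate")] + [
        SequenceRecord(f"isolate_decoy_{i}", random_protein(int(rng.integers(150, 350)), rng),
                       source="isolate")
        for i in range(5)
    ]
    enzyme = [
        SequenceRecord("hsd_query", path.variant(0.35, rng, config.indel_fraction),
                       source="characterized_enzyme"),
        SequenceRecord("enzyme_decoy", random_protein(250, rng), source="characterized_enzyme"),
    ]

    return SyntheticStudy(
        config=config,
        proteins=proteins,
        genes=genes,
        truth=truth,
        species_presence=pd.DataFrame(present,
                                      index=pd.Index(species_ids, name="species"),
                                      columns=sample_ids),
        counts=pd.DataFrame(counts, index=pd.Index(gene_lengths.index, name="gene"),
                            columns=sample_ids),
        gene_lengths=gene_lengths,
        metabolites=pd.DataFrame(index=pd.Index(sample_ids, name="sample")),
        phenotypes=pd.DataFrame(),
        isolate_proteins=isolate,
        enzyme_queries=enzyme,
        seed_used=config.seed,
    )


def simulate_metabolome(
    species_presence: pd.DataFrame,
    encoder_flags: pd.Series,
    delta: float,
    epsilon: float,
    seed: int | np.random.Generator = 0,
    reduction_range: tuple[float, float] = (0.25, 0.45),
    fold_range: tuple[float, float] = (3.3, 5.4),
) -> pd.DataFrame:
    """Per-sample sterol calls and relative abundances.

    Coprostanol is called positive with probability ``delta`` when at least
    one encoder species is present, else with the background false-positive
    rate ``epsilon``. Encoder samples have their cholesterol multiplied by a
    reduction factor drawn from ``reduction_range`` (i.e., a 55-75% drop by
    default) and cholestenone by a fold increase from ``fold_range``.
    """
    if not 0.0 <= delta <= 1.0 or not 0.0 <= epsilon <= 1.0:
        raise ValueError("delta and epsilon must lie in [0, 1]")
    flags = encoder_flags.reindex(species_presence.index)
    if flags.isna().any():
        raise ValueError("encoder flags do not match the species presence matrix")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    encoder_present = species_presence.loc[flags.astype(bool)].any(axis=0).to_numpy()
    n = species_presence.shape[1]
    p_detect = np.where(encoder_present, delta, epsilon)
    detected = rng.random(n) < p_detect
    cholesterol = rng.lognormal(0.0, 0.5, size=n)
    cholesterol[encoder_present] *= rng.uniform(*reduction_range, size=encoder_present.sum())
    cholestenone = rng.lognormal(-2.0, 0.5, size=n)
    cholestenone[encoder_present] *= rng.uniform(*fold_range, size=encoder_present.sum())
    coprostanol = np.where(detected, rng.lognormal(-1.0, 0.5, size=n), 0.0)
    return pd.DataFrame(
        {
            "coprostanol_detected": detected,
            "cholesterol": cholesterol,
            "cholestenone": cholestenone,
            "coprostanol": coprostanol,
        },
        index=pd.Index(species_presence.columns, name="sample"),
    )


def simulate_host_phenotypes(
    encoder_status,
    config: SimulationConfig,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Participant covariates and a serum lipid panel.

    TC (mmol/L) = baseline + beta * I(encoder) + sum of covariate effects +
    Normal(0, noise_sd). Covariate defaults: age ~ Normal(50, 12), sex (male)
    Bernoulli(0.5), antibiotics Bernoulli(0.1), statin Bernoulli(0.15);
    disease status (non-IBD/CD/UC) is drawn for the stool-cohort models and
    carries no TC effect unless configured.
    """
    enc = np.asarray(encoder_status, dtype=bool)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = enc.size
    age = rng.normal(50.0, 12.0, size=n)
    sex = rng.random(n) < 0.5
    antibiotics = rng.random(n) < 0.1
    statin = rng.random(n) < 0.15
    cvd = rng.random(n) < 0.2
    disease = rng.choice(["CD", "UC", "nonIBD"], size=n, p=[0.35, 0.25, 0.40])
    effects = config.covariate_effects
    numeric = {"age": age, "sex": sex.astype(float), "antibiotics": antibiotics.astype(float),
               "statin": statin.astype(float), "cvd": cvd.astype(float)}
    tc = config.baseline_tc + config.lipid_effect_beta * enc.astype(float)
    for name, beta in effects.items():
        tc = tc + beta * numeric[name]
    tc = tc + rng.normal(0.0, config.noise_sd, size=n)
    hdl = np.clip(rng.normal(1.4, 0.3, size=n), 0.5, None)
    tg = np.clip(rng.lognormal(np.log(1.2), 0.4, size=n), None, 4.4)
    return pd.DataFrame(
        {
            "age": age,
            "sex": np.where(sex, "male", "female"),
            "antibiotics": antibiotics,
            "statin": statin,
            "cvd": cvd,
            "disease": disease,
            "TC": tc,
            "HDL": hdl,
            "TG": tg,
        },
        index=pd.Index([f"P{i:04d}" for i in range(n)], name="participant"),
    )


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Full synthetic study: community counts, metabolome, and phenotypes.

    Uses a single RNG stream seeded from ``config.seed``; identical configs
    produce byte-identical bundles. Participants map 1:1 to samples unless
    ``samples_per_participant`` > 1, in which case consecutive samples share
    a participant and the participant is an encoder when any of their samples
    carries an encoder species.
    """
    rng = np.random.default_rng(config.seed)
    study = simulate_community_samples(config, rng)
    study.metabolites = simulate_metabolome(
        study.species_presence,
        study.truth["encoder"],
        config.detect_prob_delta,
        config.background_fp_epsilon,
        rng,
        config.cholesterol_reduction_range,
        config.cholestenone_fold_range,
    )
    k = max(1, config.samples_per_participant)
    sample_ids = list(study.counts.columns)
    participant_of = {s: f"P{i // k:04d}" for i, s in enumerate(sample_ids)}
    encoder_sample = (
        study.species_presence.loc[study.truth["encoder"].astype(bool)].any(axis=0)
    )
    participant_encoder = (
        encoder_sample.groupby([participant_of[s] for s in sample_ids]).any().sort_index()
    )
    study.phenotypes = simulate_host_phenotypes(participant_encoder.to_numpy(), config, rng)
    study.phenotypes.index = pd.Index(participant_encoder.index, name="participant")
    study.metabolites["participant"] = [participant_of[s] for s in sample_ids]
    return study


def simulate_encoder_converter(
    n: int,
    true_or: float,
    encoder_prevalence: float = 0.45,
    base_rate: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Encoder/converter flag pairs with a specified true odds ratio.

    Non-encoders convert with probability ``base_rate``; encoder odds are
    ``true_or`` times the non-encoder odds.
    """
    if true_or <= 0:
        raise ValueError("true odds ratio must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    encoder = rng.random(n) < encoder_prevalence
    odds0 = base_rate / (1 - base_rate)
    p1 = true_or * odds0 / (1 + true_or * odds0)
    converter = rng.random(n) < np.where(encoder, p1, base_rate)
    return encoder, converter


def _write_fasta(records: list[SequenceRecord], path: Path) -> None:
    bio = [BioSeqRecord(Seq(r.residues), id=r.id,
                        description=r.source or "") for r in records]
    SeqIO.write(bio, path, "fasta")


def _read_fasta(path: Path) -> list[SequenceRecord]:
    out = []
    for rec in SeqIO.parse(path, "fasta"):
        source = rec.description[len(rec.id):].strip() or None
        out.append(SequenceRecord(rec.id, str(rec.seq), source=source))
    return out


def write_study_bundle(study: SyntheticStudy, directory: str | Path) -> Path:
    """Write a study to a directory of plain-text files.

    Emits proteins.faa, genes.fna, counts.tsv, presence.tsv, metabolites.tsv,
    phenotypes.tsv, truth.tsv, isolate.faa, enzymes.faa, and config.json; the
    bundle round-trips losslessly through :func:`read_study_bundle`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _write_fasta(study.proteins, directory / "proteins.faa")
    _write_fasta(study.genes, directory / "genes.fna")
    _write_fasta(study.isolate_proteins, directory / "isolate.faa")
    _write_fasta(study.enzyme_queries, directory / "enzymes.faa")
    study.counts.to_csv(directory / "counts.tsv", sep="\t", index_label="gene")
    study.species_presence.astype(int).to_csv(directory / "presence.tsv", sep="\t",
                                              index_label="species")
    study.metabolites.to_csv(directory / "metabolites.tsv", sep="\t")
    study.phenotypes.to_csv(directory / "phenotypes.tsv", sep="\t")
    study.truth.to_csv(directory / "truth.tsv", sep="\t")
    cfg = dataclasses.asdict(study.config)
    cfg["seed_used"] = study.seed_used
    (directory / "config.json").write_text(json.dumps(cfg, indent=2, default=list) + "\n")
    return directory


def read_study_bundle(directory: str | Path) -> SyntheticStudy:
    """Read a bundle written by :func:`write_study_bundle`."""
    directory = Path(directory)
    cfg = json.loads((directory / "config.json").read_text())
    seed_used = cfg.pop("seed_used")
    cfg["planted_identity_range"] = tuple(cfg["planted_identity_range"])
    cfg["abundance_lognormal_mu_sigma"] = tuple(cfg["abundance_lognormal_mu_sigma"])
    cfg["cholesterol_reduction_range"] = tuple(cfg["cholesterol_reduction_range"])
    cfg["cholestenone_fold_range"] = tuple(cfg["cholestenone_fold_range"])
    if isinstance(cfg["species_prevalence"], list):
        cfg["species_prevalence"] = np.asarray(cfg["species_prevalence"])
    config = SimulationConfig(**cfg)
    proteins = _read_fasta(directory / "proteins.faa")
    genes = _read_fasta(directory / "genes.fna")
    counts = pd.read_csv(directory / "counts.tsv", sep="\t", index_col="gene")
    presence = pd.read_csv(directory / "presence.tsv", sep="\t", index_col="species")
    metabolites = pd.read_csv(directory / "metabolites.tsv", sep="\t", index_col="sample")
    phenotypes = pd.read_csv(directory / "phenotypes.tsv", sep="\t", index_col="participant")
    truth = pd.read_csv(directory / "truth.tsv", sep="\t", index_col="species",
                        keep_default_na=False)
    truth["encoder"] = truth["encoder"].astype(bool) if truth["encoder"].dtype == bool else (
        truth["encoder"].astype(str).isin(["True", "true", "1"])
    )
    gene_lengths = pd.Series({g.id: g.length for g in genes}).reindex(counts.index)
    return SyntheticStudy(
        config=config,
        proteins=proteins,
        genes=genes,
        truth=truth,
        species_presence=presence.astype(bool),
        counts=counts,
        gene_lengths=gene_lengths,
        metabolites=metabolites,
        phenotypes=phenotypes,
        isolate_proteins=_read_fasta(directory / "isolate.faa"),
        enzyme_queries=_read_fasta(directory / "enzymes.faa"),
        seed_used=seed_used,
    )
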