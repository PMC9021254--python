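"""Synthetic paired plaque/saliva-style cohorts with known ground truth.

The generator emulates the statistical structure the downstream compositional
analysis assumes about a periodontal 16S cohort:

* each participant contributes one shallow-pocket plaque sample and, for a
  fraction of participants, an additional deep-pocket sample;
* feature (ASV) counts follow a multinomial-logit model: per-feature baseline
  log-abundances are drawn once, deep-site samples add planted log-scale
  differentials, a per-participant latent *severity* scales the same
  differentials (so dysbiosis varies continuously across people, including at
  shallow sites), softmax gives relative abundances, and counts are drawn
  multinomially with a log-normally distributed total read count (microbial
  load proxy) spanning orders of magnitude;
* features belong to genera with shared lineages; the first genus is labelled
  *Treponema* and carries positive deep-site effects, the second
  *Corynebacterium* with negative effects, so the planted log-ratio indicator
  has a known deep-vs-shallow contrast;
* clinical covariates are linear in the participant-level true log-ratio with
  tunable coupling slopes, plus confounder terms (age, sex, BMI, smoking) and
  Gaussian noise.

Everything is drawn from a single :class:`numpy.random.Generator` stream, so a
design with the same seed reproduces byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "CohortDesign",
    "GroundTruth",
    "simulate_cohort",
    "simulate_fastq",
    "planted_design",
    "null_design",
    "TREPONEMA_GENUS",
    "CORYNEBACTERIUM_GENUS",
]

TREPONEMA_GENUS = "Treponema"
CORYNEBACTERIUM_GENUS = "Corynebacterium"

_OTHER_GENERA = (
    "Streptococcus",
    "Actinomyces",
    "Veillonella",
    "Fusobacterium",
    "Prevotella",
    "Neisseria",
    "Rothia",
    "Tannerella",
    "Capnocytophaga",
    "Porphyromonas",
    "Campylobacter",
    "Eubacterium",
)


def _default_coupling() -> dict[str, float]:
    # slope per natural-log unit of the true Treponema/Corynebacterium ratio
    return {
        "pct_bop": 0.03,
        "attachment_loss_mm": 0.05,
        "meansbp": 2.0,
        "meandbp": 1.5,
        "glucose": 0.0,
        "insulin": 0.3,
        "hba1c": 0.0,
    }


def _default_noise_sd() -> dict[str, float]:
    return {
        "pct_bop": 0.08,
        "attachment_loss_mm": 0.30,
        "meansbp": 5.0,
        "meandbp": 4.0,
        "glucose": 6.0,
        "insulin": 2.5,
        "hba1c": 0.25,
    }


@dataclass
class CohortDesign:
    """Parameters of a synthetic cohort.

    Defaults are sized like a desk-scale analogue of an epidemiological oral
    microbiome cohort: 100 participants, all with a paired deep site, 100
    features in 10 genera, ±2 natural-log planted effects on the two indicator
    genera, and total counts log-normal over ≥2 orders of magnitude.
    """

    n_participants: int = 100
    frac_with_deep_site: float = 1.0
    n_features: int = 100
    n_genera: int = 10
    treponema_effect: float = 2.0
    corynebacterium_effect: float = -2.0
    background_effect_sd: float = 0.25
    planted_differentials: dict[str, float] | None = None
    baseline_sd: float = 0.8
    genus_sd: float = 0.5
    sample_noise_sd: float = 0.5
    severity_sd: float = 0.5
    load_lognormal_mu: float = 8.5
    load_lognormal_sigma: float = 1.25
    coupling: dict[str, float] = field(default_factory=_default_coupling)
    noise_sd: dict[str, float] = field(default_factory=_default_noise_sd)
    overdispersion: float = 0.0
    confounded: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        if not 0.0 <= self.frac_with_deep_site <= 1.0:
            raise ValueError("frac_with_deep_site must be in [0, 1]")
        if self.n_genera < 2 or self.n_features < self.n_genera:
            raise ValueError("need n_features >= n_genera >= 2")
        if self.load_lognormal_sigma < 0 or self.sample_noise_sd < 0:
            raise ValueError("scale parameters must be nonnegative")


def null_design(**overrides) -> CohortDesign:
    """A design with no planted effects and no covariate coupling.

    Deep and shallow samples are exchangeable; every covariate is pure noise.
    """
    base = dict(
        treponema_effect=0.0,
        corynebacterium_effect=0.0,
        background_effect_sd=0.0,
        severity_sd=0.0,
        coupling={k: 0.0 for k in _default_coupling()},
    )
    base.update(overrides)
    return CohortDesign(**base)


def planted_design(**overrides) -> CohortDesign:
    """The canonical planted cohort: 200 samples, 100 features, ±2 effects."""
    return CohortDesign(**overrides)


@dataclass
class GroundTruth:
    """What the generator actually planted, for downstream recovery checks.

    ``true_differentials`` are deep-vs-shallow natural-log effects (positive =
    enriched in deep pockets); the shallow-pole orientation used by the
    differential ranker is their negation.
    """

    true_differentials: pd.Series
    relative_abundance: pd.DataFrame  # samples × features, rows sum to 1
    load: pd.Series
    true_log_ratio: pd.Series  # per-sample ln(Treponema/Corynebacterium), pre-sampling
    severity: pd.Series  # per-participant latent severity
    participant_log_ratio: pd.Series  # mean true log-ratio over a participant's sites


def _lineage(genus: str, phylum: str, species: str) -> str:
    return (
        f"k__Bacteria; p__{phylum}; c__{phylum}ia; o__{genus}ales; "
        f"f__{genus}aceae; g__{genus}; s__{genus}_{species}"
    )


def _random_coalescent(labels: list[str], rng: np.random.Generator) -> TreeNode:
    """Random binary tree over ``labels`` with exponential branch lengths."""
    nodes = [TreeNode(name=lab, length=float(rng.exponential(0.1)) ) for lab in labels]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        parent = TreeNode(length=float(rng.exponential(0.1)), children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.length = None
    return root


def simulate_cohort(design: CohortDesign):
    """Draw a full synthetic cohort.

    Returns
    -------
    (table, metadata, taxonomy, tree, truth)
        ``table`` is a samples × features integer DataFrame, ``metadata`` a
        per-sample DataFrame indexed by sample_id, ``taxonomy`` a feature →
        lineage Series, ``tree`` a rooted :class:`skbio.TreeNode` whose genus
        features form clades, and ``truth`` a :class:`GroundTruth`.
    """
    rng = np.random.default_rng(design.seed)
    P, D, G = design.n_participants, design.n_features, design.n_genera

    feature_ids = [f"ASV{j:04d}" for j in range(D)]
    genus_names = [TREPONEMA_GENUS, CORYNEBACTERIUM_GENUS] + [
        _OTHER_GENERA[k % len(_OTHER_GENERA)] + ("" if k < len(_OTHER_GENERA) else str(k))
        for k in range(G - 2)
    ]
    genus_of = np.sort(np.arange(D) % G)  # contiguous, near-balanced genus blocks
    phyla = ["Spirochaetes", "Actinobacteria", "Firmicutes", "Bacteroidetes", "Proteobacteria"]
    taxonomy = pd.Series(
        {
            fid: _lineage(genus_names[g], phyla[g % len(phyla)], f"sp{j:03d}")
            for j, (fid, g) in enumerate(zip(feature_ids, genus_of))
        },
        name="lineage",
    )

    # planted deep-vs-shallow log effects
    if design.planted_differentials is not None:
        d = pd.Series(0.0, index=feature_ids)
        for fid, v in design.planted_differentials.items():
            d.loc[fid] = float(v)
        d = d.to_numpy()
    else:
        d = np.where(
            genus_of == 0,
            design.treponema_effect,
            np.where(genus_of == 1, design.corynebacterium_effect, 0.0),
        ).astype(float)
        if design.background_effect_sd > 0:
            bg = rng.normal(0.0, design.background_effect_sd, size=D)
            d = d + np.where((genus_of != 0) & (genus_of != 1), bg, 0.0)

    genus_offset = rng.normal(0.0, design.genus_sd, size=G)
    baseline = genus_offset[genus_of] + rng.normal(0.0, design.baseline_sd, size=D)

    # participants and sites
    has_deep = rng.random(P) < design.frac_with_deep_site
    severity = rng.normal(0.0, 1.0, size=P)

    # participant-level demographics / confounders
    age = np.clip(rng.normal(50.0, 10.0, size=P), 25.0, 75.0)
    sex = rng.choice(["female", "male"], size=P)
    race = rng.choice(["groupA", "groupB", "groupC"], size=P, p=[0.5, 0.3, 0.2])
    smoking = rng.choice(["never", "former", "current"], size=P, p=[0.87, 0.08, 0.05])
    bmi = np.clip(rng.normal(27.0, 4.0, size=P), 17.0, 45.0)

    if design.confounded:
        severity = severity + 0.02 * (age - 50.0) + 0.5 * (smoking == "current")

    participant_ids = [f"P{i:04d}" for i in range(P)]
    sample_rows = []  # (sample_id, participant_idx, is_deep)
    for i, pid in enumerate(participant_ids):
        sample_rows.append((f"{pid}.S", i, 0))
        if has_deep[i]:
            sample_rows.append((f"{pid}.D", i, 1))
    sample_ids = [r[0] for r in sample_rows]
    part_idx = np.array([r[1] for r in sample_rows])
    is_deep = np.array([r[2] for r in sample_rows])
    n_samples = len(sample_ids)

    # log-abundances and relative abundances
    eff = d[None, :] * (is_deep[:, None] + design.severity_sd * severity[part_idx, None])
    eta = baseline[None, :] + eff + rng.normal(0.0, design.sample_noise_sd, size=(n_samples, D))
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)

    load = np.maximum(
        rng.lognormal(design.load_lognormal_mu, design.load_lognormal_sigma, size=n_samples), 10.0
    ).astype(np.int64)

    counts = np.empty((n_samples, D), dtype=np.int64)
    for i in range(n_samples):
        pi = p[i]
        if design.overdispersion > 0:
            alpha = pi * max(1.0 / design.overdispersion, 1e-6)
            pi = rng.dirichlet(np.maximum(alpha, 1e-8))
        counts[i] = rng.multinomial(load[i], pi)
    table = pd.DataFrame(counts, index=sample_ids, columns=feature_ids)
    table.index.name = "sample_id"
    table.columns.name = "feature_id"

    # true per-sample log-ratio of the two indicator genera (pre-sampling)
    num = p[:, genus_of == 0].sum(axis=1)
    den = p[:, genus_of == 1].sum(axis=1)
    true_lr = pd.Series(np.log(num / den), index=sample_ids)
    part_lr = true_lr.groupby(pd.Series(part_idx, index=sample_ids)).mean()
    part_lr.index = [participant_ids[i] for i in part_lr.index]
    part_lr = pd.Series(part_lr, index=participant_ids)

    # clinical covariates, coupled to the participant-level true log-ratio
    lr_c = part_lr.to_numpy() - part_lr.to_numpy().mean()
    cpl, nsd = design.coupling, design.noise_sd

    def cov(name, intercept, extra=0.0, clip=None):
        v = (
            intercept
            + cpl.get(name, 0.0) * lr_c
            + extra
            + rng.normal(0.0, nsd.get(name, 0.0), size=P)
        )
        if clip is not None:
            v = np.clip(v, *clip)
        return v

    pct_bop = cov("pct_bop", 0.28, clip=(0.0, 1.0))
    attach = cov("attachment_loss_mm", 0.6, clip=(0.0, None))
    meansbp = cov("meansbp", 117.0, extra=0.3 * (age - 50.0) + 0.3 * (bmi - 27.0))
    meandbp = cov("meandbp", 72.0, extra=0.15 * (age - 50.0))
    glucose = cov("glucose", 85.0, extra=0.2 * (bmi - 27.0))
    insulin = cov("insulin", 8.0, extra=0.25 * (bmi - 27.0), clip=(0.5, None))
    homa_ir = glucose * insulin / 405.0
    hba1c = cov("hba1c", 5.3, clip=(3.5, None))

    # site-level pocket depth consistent with the site class labels
    pocket = np.where(
        is_deep == 1,
        np.clip(rng.normal(5.0, 0.8, size=n_samples), 4.0, 10.0),
        np.clip(rng.normal(2.0, 0.4, size=n_samples), 0.5, 2.9),
    )

    meta = pd.DataFrame(
        {
            "participant_id": [participant_ids[i] for i in part_idx],
            "site_class": np.where(is_deep == 1, "deep", "shallow"),
            "pocket_depth_mm": pocket,
            "attachment_loss_mm": attach[part_idx],
            "pct_bop": pct_bop[part_idx],
            "meansbp": meansbp[part_idx],
            "meandbp": meandbp[part_idx],
            "glucose": glucose[part_idx],
            "insulin": insulin[part_idx],
            "homa_ir": homa_ir[part_idx],
            "hba1c": hba1c[part_idx],
            "age": age[part_idx],
            "sex": sex[part_idx],
            "race": race[part_idx],
            "smoking": smoking[part_idx],
            "bmi": bmi[part_idx],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # genus-clade coalescent tree
    genus_clades = []
    for g in range(G):
        labs = [feature_ids[j] for j in range(D) if genus_of[j] == g]
        clade = _random_coalescent(labs, rng)
        clade.length = float(rng.exponential(0.2))
        genus_clades.append(clade)
    backbone = _random_coalescent([f"__genus{g}" for g in range(G)], rng)
    for tip in list(backbone.tips()):
        g = int(tip.name.removeprefix("__genus"))
        clade = genus_clades[g]
        clade.length = tip.length
        parent = tip.parent
        parent.remove(tip)
        parent.append(clade)
    tree = backbone
    tree.length = None

    truth = GroundTruth(
        true_differentials=pd.Series(d, index=feature_ids),
        relative_abundance=pd.DataFrame(p, index=sample_ids, columns=feature_ids),
        load=pd.Series(load, index=sample_ids),
        true_log_ratio=true_lr,
        severity=pd.Series(severity, index=participant_ids),
        participant_log_ratio=part_lr,
    )
    return table, meta, taxonomy, tree, truth


def design_to_dict(design: CohortDesign) -> dict:
    return dataclasses.asdict(design)


def simulate_fastq(n_reads: int, length: int, bad_run_positions, seed: int = 0):
    """Generate FASTQ records for exercising the quality-trim stage.

    Every read gets a run of 3 bases with PHRED 2 starting at each 0-based
    position in ``bad_run_positions``; all other bases have PHRED ≥ 30.
    Returns a list of ``(read_id, sequence, phred_scores)`` tuples (see
    :mod:`periomip.io` for FASTQ serialization at offset 33).
    """
    positions = list(bad_run_positions)
    for pos in positions:
        if not 0 <= pos < length:
            raise ValueError(f"bad run position {pos} outside read of length {length}")
    rng = np.random.default_rng(seed)
    reads = []
    bases = np.array(list("ACGT"))
    for i in range(n_reads):
        seq = "".join(rng.choice(bases, size=length))
        qual = rng.integers(30, 41, size=length)
        for pos in positions:
            qual[pos : pos + 3] = 2
        reads.append((f"read{i:05d}", seq, qual.tolist()))
    return reads
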