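"""Synthetic two-group expression studies with planted ceRNA structure.

The generator emulates a 3-vs-3 H2O2-exposure design at desk scale: three
count matrices (circRNA BSJ counts, mRNA counts, miRNA counts) drawn from
negative-binomial distributions with log-normal library-size factors,
circRNA and mature-miRNA sequences, a TargetScan-like miRNA->gene table, and
a disease-associated miRNA list - together with a ``SyntheticTruth`` record
of everything that was planted, so recovery can be scored exactly.

Planted structure
-----------------
* DE features: a fraction of circRNAs and mRNAs get a linear fold change
  ``planted_fc`` (random sign) applied to the treated group.
* ceRNA axes: ``n_planted_axes`` triples (circ, miR, gene) are realized by
  (i) adding the (miR, gene) row to the target table, (ii) embedding an
  8mer seed site for that miRNA in the circRNA sequence (sometimes across
  the back-spliced junction), and (iii) guaranteeing the miRNA passes the
  expression rule. Axis members are forced into the DE sets with a shared
  fold-change direction.
* Co-expression: each planted pair shares a per-sample latent factor that
  multiplies both members' means. The factor is centered within each
  treatment group, so it drives correlation across all six samples without
  biasing the estimated fold change - coordinated regulation orthogonal to
  the treatment contrast.
* Decoys: extra (miR, gene) target rows and extra seed sites are planted at
  ``decoy_interaction_rate`` so that false axes are reachable, and random
  sequence background contributes coincidental seed matches.
* Disease annotation: miRNAs involved in planted or decoy sponge sites are
  disease-annotated with odds raised by ``assoc_enrichment_odds`` over the
  baseline rate, giving the sponge/disease Fisher table a tunable signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .cerna_network import CeRNAAxis
from .expression_io import (
    AnnotationList,
    CONTROL,
    CountMatrix,
    TREATED,
    write_annotation_list,
    write_count_matrix,
    write_fasta,
    write_target_table,
)
from .target_prediction import expressed_mirnas, reverse_complement, scan_mre

_NT = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Generation parameters; defaults are the study-scale conditions.

    ``dispersion`` is the NB phi (Var = mu + phi*mu^2); ``latent_sd`` is the
    standard deviation of the per-sample latent factor shared by planted
    pair members and ``latent_beta`` its amplitude on the natural-log scale;
    ``decoy_interaction_rate`` scales both decoy target-table rows and decoy
    seed sites; ``assoc_enrichment_odds`` is the odds ratio by which sponge
    miRNAs are enriched in the disease list over ``assoc_baseline_rate``.
    """

    seed: int = 0
    n_per_group: int = 3
    n_circ: int = 150
    n_mrna: int = 400
    n_mirna: int = 80
    frac_de: float = 0.08
    planted_fc: float = 4.0
    dispersion: float = 0.1
    n_planted_axes: int = 30
    latent_sd: float = 0.4
    latent_beta: float = 4.0
    decoy_interaction_rate: float = 0.002
    assoc_enrichment_odds: float = 4.0
    assoc_baseline_rate: float = 0.2
    circ_seq_len: int = 150
    mirna_len: int = 22
    planted_min_mean: float = 200.0  # abundance floor for planted-axis members

    def __post_init__(self) -> None:
        if min(self.n_per_group, self.n_circ, self.n_mrna, self.n_mirna) < 1:
            raise ValueError("all counts must be positive")
        if not (0 <= self.frac_de <= 1 and 0 <= self.decoy_interaction_rate <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.planted_fc <= 1:
            raise ValueError("planted_fc must exceed 1")
        if self.dispersion <= 0 or self.latent_sd < 0:
            raise ValueError("dispersion must be > 0 and latent_sd >= 0")
        if self.n_planted_axes > min(self.n_circ, self.n_mrna, self.n_mirna):
            raise ValueError("more planted axes than available circ/gene/miRNA triples")

    @classmethod
    def low_noise(cls, seed: int = 0, **kw) -> "SimConfig":
        """Low-dispersion, strong-effect preset used for recovery scoring."""
        kw.setdefault("dispersion", 0.05)
        kw.setdefault("planted_fc", 8.0)
        kw.setdefault("latent_sd", 0.6)
        return cls(seed=seed, **kw)


@dataclass(frozen=True)
class SyntheticTruth:
    """Everything planted, keyed by feature ID."""

    de_circ: dict[str, float] = field(hash=False)  # id -> signed log2 FC
    de_mrna: dict[str, float] = field(hash=False)
    planted_pairs: frozenset[tuple[str, str]] = frozenset()
    planted_axes: frozenset[CeRNAAxis] = frozenset()
    expressed_mirnas: frozenset[str] = frozenset()
    config: SimConfig = SimConfig()


@dataclass
class SyntheticDataset:
    circ_counts: CountMatrix
    mrna_counts: CountMatrix
    mirna_counts: CountMatrix
    circ_seqs: dict[str, str]
    mirna_seqs: dict[str, str]
    target_table: set[tuple[str, str]]
    disease_mirnas: AnnotationList
    truth: SyntheticTruth


@dataclass(frozen=True)
class RecoveryScore:
    precision: float
    recall: float
    f1: float
    empty_prediction: bool = False


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_NT, size=length))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Vectorized NB(mu, phi) draw; mean 0 yields 0."""
    r = 1.0 / phi
    p = np.where(mean > 0, r / (r + mean), 1.0)
    return rng.negative_binomial(r, p)


def _sample_ids(n_per_group: int) -> tuple[list[str], dict[str, str]]:
    ctrl = [f"ctrl_{i + 1}" for i in range(n_per_group)]
    h2o2 = [f"h2o2_{i + 1}" for i in range(n_per_group)]
    groups = {s: CONTROL for s in ctrl} | {s: TREATED for s in h2o2}
    return ctrl + h2o2, groups


def _embed_site(seq: list[str], mirna: str, start: int) -> None:
    """Write an 8mer site (m8 match + seed match + A1) at ``start``, modularly."""
    site = reverse_complement(mirna[:8].replace("U", "T"))[:-1] + "A"
    # revcomp of positions 1-8 puts the m8 complement first and the base
    # opposite position 1 last; forcing that last base to 'A' makes the 8mer
    L = len(seq)
    for k, base in enumerate(site):
        seq[(start + k) % L] = base


def simulate(config: SimConfig) -> SyntheticDataset:
    """Generate a complete synthetic study; byte-reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_per_group
    samples, groups = _sample_ids(n)
    n_samples = 2 * n
    treated_mask = np.array([groups[s] == TREATED for s in samples])

    # ---- identifiers -----------------------------------------------------
    circ_ids: list[str] = []
    seen = set()
    while len(circ_ids) < config.n_circ:
        chrom = f"chr{rng.integers(1, 23)}"
        start = int(rng.integers(10_000, 200_000_000))
        cid = f"{chrom}:{start}|{start + int(rng.integers(200, 5000))}"
        if cid not in seen:
            seen.add(cid)
            circ_ids.append(cid)
    gene_ids = [f"GENE{i + 1:04d}" for i in range(config.n_mrna)]
    mirna_ids = [f"hsa-miR-{i + 1:03d}-5p" for i in range(config.n_mirna)]

    # ---- planted axes ----------------------------------------------------
    ax_circ = rng.choice(config.n_circ, size=config.n_planted_axes, replace=False)
    ax_mir = rng.choice(config.n_mirna, size=config.n_planted_axes, replace=False)
    ax_gene = rng.choice(config.n_mrna, size=config.n_planted_axes, replace=False)
    planted_axes = frozenset(
        CeRNAAxis(circ_ids[c], mirna_ids[mi], gene_ids[g])
        for c, mi, g in zip(ax_circ, ax_mir, ax_gene)
    )
    planted_pairs = frozenset((a.circ_id, a.gene_id) for a in planted_axes)

    # ---- sequences -------------------------------------------------------
    mirna_seqs = {m: _random_seq(rng, config.mirna_len) for m in mirna_ids}
    circ_seq_arr = {c: list(_random_seq(rng, config.circ_seq_len)) for c in circ_ids}
    written: dict[str, set[int]] = {c: set() for c in circ_ids}  # occupied positions

    def _plant_site(circ: str, mirna: str) -> bool:
        L = config.circ_seq_len
        for _ in range(60):
            start = int(rng.integers(0, L))
            span = {(start + k) % L for k in range(9)}
            if span.isdisjoint(written[circ]):
                _embed_site(circ_seq_arr[circ], mirna_seqs[mirna], start)
                written[circ] |= span
                return True
        return False

    for a in sorted(planted_axes):
        if not _plant_site(a.circ_id, a.mirna_id):
            raise RuntimeError(f"could not place a seed site on {a.circ_id}; sequence too short")

    n_decoy_sites = int(round(config.decoy_interaction_rate * config.n_circ * config.n_mirna))
    planted_cm = {(a.circ_id, a.mirna_id) for a in planted_axes}
    decoy_site_mirnas: set[str] = set()
    for _ in range(n_decoy_sites):
        c = circ_ids[int(rng.integers(config.n_circ))]
        mi = mirna_ids[int(rng.integers(config.n_mirna))]
        if (c, mi) not in planted_cm and _plant_site(c, mi):
            decoy_site_mirnas.add(mi)  # best effort; crowded sequences may refuse

    circ_seqs = {c: "".join(arr) for c, arr in circ_seq_arr.items()}

    # ---- differential expression assignment ------------------------------
    lfc = float(np.log2(config.planted_fc))
    de_circ: dict[str, float] = {}
    de_mrna: dict[str, float] = {}
    axis_sign = {}
    for a in sorted(planted_axes):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        axis_sign[a] = sign
        de_circ[a.circ_id] = sign * lfc
        de_mrna[a.gene_id] = sign * lfc

    def _add_decoy_de(ids: list[str], de: dict[str, float], n_total: int) -> None:
        n_extra = int(round(config.frac_de * n_total))
        free = [i for i in ids if i not in de]
        pick = rng.choice(len(free), size=min(n_extra, len(free)), replace=False)
        for i in pick:
            de[free[int(i)]] = (1.0 if rng.random() < 0.5 else -1.0) * lfc

    _add_decoy_de(circ_ids, de_circ, config.n_circ)
    _add_decoy_de(gene_ids, de_mrna, config.n_mrna)

    # ---- per-sample mean structure ---------------------------------------
    size_factors = np.exp(rng.normal(0.0, 0.2, size=n_samples))
    size_factors /= np.exp(np.mean(np.log(size_factors)))

    def _base_means(n_feat: int, meanlog: float, sdlog: float, lo: float, hi: float) -> np.ndarray:
        return np.clip(rng.lognormal(meanlog, sdlog, size=n_feat), lo, hi)

    circ_mu = _base_means(config.n_circ, np.log(60), 1.0, 0.2, 2000)
    # a background tail of unreliable, low-count circRNAs for the junction filter
    low = rng.random(config.n_circ) < 0.25
    circ_mu[low] = np.minimum(circ_mu[low], rng.uniform(0.05, 0.8, size=int(low.sum())))
    mrna_mu = _base_means(config.n_mrna, np.log(200), 1.2, 0.5, 1500)
    mirna_mu = _base_means(config.n_mirna, np.log(50), 1.0, 0.05, 1500)
    mirna_low = rng.random(config.n_mirna) < 0.30
    mirna_mu[mirna_low] = np.minimum(mirna_mu[mirna_low], 0.2)

    circ_index = {c: i for i, c in enumerate(circ_ids)}
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    mirna_index = {m: i for i, m in enumerate(mirna_ids)}

    for a in planted_axes:  # planted members must be quantifiable
        fl = config.planted_min_mean
        circ_mu[circ_index[a.circ_id]] = max(circ_mu[circ_index[a.circ_id]], fl)
        mrna_mu[gene_index[a.gene_id]] = max(mrna_mu[gene_index[a.gene_id]], fl)
        mirna_mu[mirna_index[a.mirna_id]] = max(mirna_mu[mirna_index[a.mirna_id]], 20.0)

    def _mean_matrix(mu: np.ndarray, de: dict[str, float], ids: list[str]) -> np.ndarray:
        m = np.outer(mu, size_factors)
        for fid, signed_lfc in de.items():
            i = ids.index(fid)
            m[i, treated_mask] *= 2.0 ** signed_lfc
        return m

    circ_mean = _mean_matrix(circ_mu, de_circ, circ_ids)
    mrna_mean = _mean_matrix(mrna_mu, de_mrna, gene_ids)
    mirna_mean = np.outer(mirna_mu, size_factors)

    # Shared latent factor per planted pair: one centered per-replicate
    # pattern applied to BOTH groups (replicate k of treated and control get
    # the same multiplier). This makes the factor exactly orthogonal to the
    # treatment contrast - it drives cross-sample correlation between the
    # pair members without adding between-group noise to fold-change
    # estimates or group sums.
    for a in sorted(planted_axes):
        z = rng.normal(0.0, config.latent_sd, size=n)
        z -= z.mean()
        bump = np.exp(config.latent_beta * np.concatenate([z, z]))
        circ_mean[circ_index[a.circ_id]] *= bump
        mrna_mean[gene_index[a.gene_id]] *= bump

    phi = config.dispersion
    circ_counts = pd.DataFrame(_nb_draw(rng, circ_mean, phi), index=circ_ids, columns=samples)
    mrna_counts = pd.DataFrame(_nb_draw(rng, mrna_mean, phi), index=gene_ids, columns=samples)
    mirna_counts = pd.DataFrame(_nb_draw(rng, mirna_mean, phi), index=mirna_ids, columns=samples)

    # guarantee the expression rule for planted miRNAs (discoverability)
    for a in planted_axes:
        row = mirna_counts.loc[a.mirna_id]
        if (row >= 1).sum() < n:  # half of 2n samples
            mirna_counts.loc[a.mirna_id] = np.maximum(row.values, 1)

    circ_cm = CountMatrix(circ_counts, dict(groups))
    mrna_cm = CountMatrix(mrna_counts, dict(groups))
    mirna_cm = CountMatrix(mirna_counts, dict(groups))

    # ---- target table and disease list -----------------------------------
    target_table = {(a.mirna_id, a.gene_id) for a in planted_axes}
    n_decoy_rows = int(round(config.decoy_interaction_rate * config.n_mirna * config.n_mrna))
    while len(target_table) < config.n_planted_axes + n_decoy_rows:
        target_table.add(
            (mirna_ids[int(rng.integers(config.n_mirna))], gene_ids[int(rng.integers(config.n_mrna))])
        )

    # miRNAs with a planted or decoy sponge site get elevated disease odds
    sponge_mirnas = {a.mirna_id for a in planted_axes} | decoy_site_mirnas
    p0 = config.assoc_baseline_rate
    odds1 = config.assoc_enrichment_odds * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    disease = {
        m for m in mirna_ids
        if rng.random() < (p1 if m in sponge_mirnas else p0)
    }
    disease_list = AnnotationList(frozenset(disease), label="disease_associated")

    expressed = frozenset(expressed_mirnas(mirna_cm))

    truth = SyntheticTruth(
        de_circ=de_circ,
        de_mrna=de_mrna,
        planted_pairs=planted_pairs,
        planted_axes=planted_axes,
        expressed_mirnas=expressed,
        config=config,
    )
    ds = SyntheticDataset(
        circ_counts=circ_cm,
        mrna_counts=mrna_cm,
        mirna_counts=mirna_cm,
        circ_seqs=circ_seqs,
        mirna_seqs={m: s.replace("T", "U") for m, s in mirna_seqs.items()},
        target_table=target_table,
        disease_mirnas=disease_list,
        truth=truth,
    )
    _assert_discoverable(ds)
    return ds


def _assert_discoverable(ds: SyntheticDataset) -> None:
    """Every planted axis must be recoverable in principle."""
    for a in ds.truth.planted_axes:
        sites = scan_mre(ds.circ_seqs[a.circ_id], ds.mirna_seqs[a.mirna_id],
                         circ_id=a.circ_id, mirna_id=a.mirna_id)
        if not any(s.site_type in {"7mer-A1", "7mer-m8", "8mer"} for s in sites):
            raise AssertionError(f"planted site for {a} not recoverable by the scanner")
        if (a.mirna_id, a.gene_id) not in ds.target_table:
            raise AssertionError(f"planted target row for {a} missing")
        if a.mirna_id not in ds.truth.expressed_mirnas:
            raise AssertionError(f"planted miRNA {a.mirna_id} fails the expression rule")


def score_recovery(
    truth: SyntheticTruth, predicted_axes: Iterable[CeRNAAxis]
) -> RecoveryScore:
    """Set precision/recall/F1 of predicted axis triples against the truth."""
    predicted = set(predicted_axes)
    true = set(truth.planted_axes)
    if not predicted:
        return RecoveryScore(0.0, 0.0, 0.0, empty_prediction=True)
    tp = len(predicted & true)
    precision = tp / len(predicted)
    recall = tp / len(true) if true else 0.0
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return RecoveryScore(precision, recall, f1)


# -- serialization ---------------------------------------------------------


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every pipeline input dialect plus the truth under ``truth/``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    paths = {
        "circ_counts": write_count_matrix(ds.circ_counts, outdir / "circ_counts.tsv"),
        "mrna_counts": write_count_matrix(ds.mrna_counts, outdir / "mrna_counts.tsv"),
        "mirna_counts": write_count_matrix(ds.mirna_counts, outdir / "mirna_counts.tsv"),
        "circ_fasta": write_fasta(ds.circ_seqs, outdir / "circ.fasta"),
        "mirna_fasta": write_fasta(ds.mirna_seqs, outdir / "mirna.fasta"),
        "target_table": write_target_table(ds.target_table, outdir / "targets.tsv"),
        "disease_mirnas": write_annotation_list(ds.disease_mirnas, outdir / "disease_mirnas.txt"),
    }
    groups_path = outdir / "groups.tsv"
    with open(groups_path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for s in ds.circ_counts.sample_ids:
            fh.write(f"{s}\t{ds.circ_counts.groups[s]}\n")
    paths["groups"] = groups_path

    t = ds.truth
    pd.DataFrame(sorted(t.de_circ.items()), columns=["feature_id", "log2_fc"]).to_csv(
        outdir / "truth" / "de_circ.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(t.de_mrna.items()), columns=["feature_id", "log2_fc"]).to_csv(
        outdir / "truth" / "de_mrna.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(t.planted_pairs), columns=["circ_id", "gene_id"]).to_csv(
        outdir / "truth" / "planted_pairs.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted((a.circ_id, a.mirna_id, a.gene_id) for a in t.planted_axes),
        columns=["circ_id", "mirna_id", "gene_id"],
    ).to_csv(outdir / "truth" / "planted_axes.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(t.expressed_mirnas), columns=["mirna_id"]).to_csv(
        outdir / "truth" / "expressed_mirnas.tsv", sep="\t", index=False)
    pd.Series(asdict(t.config)).to_json(outdir / "truth" / "sim_config.json", indent=2)
    return paths


def read_truth_axes(outdir: str | Path) -> frozenset[CeRNAAxis]:
    df = pd.read_csv(Path(outdir) / "truth" / "planted_axes.tsv", sep="\t")
    return frozenset(CeRNAAxis(r.circ_id, r.mirna_id, r.gene_id) for r in df.itertuples())
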