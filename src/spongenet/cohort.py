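"""Synthetic multi-omic cohort generation with known ground truth.

The generator emulates a tumor/normal RNA-seq cohort (mRNA + lncRNA + miRNA)
in which every downstream analysis has a planted, recoverable answer:

* negative-binomial counts around lognormal per-feature means, with
  lognormal library-size factors;
* tumor-vs-normal differential expression for a configurable fraction of
  features at a fixed log2 fold change;
* ceRNA sponge triplets on a latent scale: miRNA abundance ``m`` is drawn
  first, free miRNA is ``f = m * (1 - sponge_strength * u)`` where ``u`` is
  the rank-scaled lncRNA level, and the target mRNA mean is multiplied by
  ``exp(-k * f / mean(f))`` — so the lncRNA de-represses the target by
  titrating miRNA away from it;
* monotone per-stage offsets (II < III < IV) for stage-trend features;
* lymph-node-metastasis (LNM) signal, both as standalone shifted features
  and through coexpression-module factors whose mean shifts in LNM tumors;
* correlated coexpression blocks sharing a latent factor with pairwise
  latent correlation ``within_module_cor``.

A single global seed drives a hierarchy of independent substreams (means,
design, sponge latents, module factors, counts, ...), so enlarging one block
does not reshuffle the others, and the same seed reproduces the cohort
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .io import (
    ExpressionMatrix,
    dedup_interactions,
    read_expression_tsv,
    read_metadata_tsv,
    write_expression_tsv,
    write_metadata_tsv,
)

STAGES = ("II", "III", "IV")


class CohortSpec(BaseModel):
    """Parameters of one synthetic cohort.

    Defaults mirror the composition of a typical prostate-cancer cohort
    (489 tumors / 52 normals; stages II:III:IV about 116:238:8; roughly one
    in five tumors lymph-node positive) at desk-scale feature counts.
    """

    model_config = ConfigDict(extra="forbid")

    n_tumor: int = Field(489, gt=0)
    n_normal: int = Field(52, gt=0)
    n_mrna: int = Field(500, gt=0)
    n_lncrna: int = Field(100, gt=0)
    n_mirna: int = Field(50, gt=0)
    n_sponge_triplets: int = Field(5, ge=0)
    sponge_strength: float = Field(0.8, ge=0.0, le=1.0)
    sponge_k: float = Field(3.0, gt=0.0)
    de_fraction: float = Field(0.2, gt=0.0, lt=1.0)
    de_log2fc: float = Field(2.0, gt=0.0)
    nb_dispersion: float = Field(0.1, gt=0.0)
    stage_probs: tuple[float, float, float] = (116 / 362, 238 / 362, 8 / 362)
    lnm_rate: float = Field(75 / 367, gt=0.0, lt=1.0)
    n_lnm_informative: int = Field(10, ge=0)
    lnm_log2fc: float = Field(1.0, gt=0.0)
    n_stage_features: int = Field(10, ge=0)
    stage_log2fc: float = Field(1.0, gt=0.0)
    module_sizes: tuple[int, ...] = (30, 30)
    within_module_cor: float = Field(0.9, gt=0.0, lt=1.0)
    module_factor_lnm_shift: float = Field(1.0, ge=0.0)
    mean_log2_expr: float = 6.0
    sd_log2_expr: float = Field(1.5, gt=0.0)
    bio_noise_sd: float = Field(0.5, ge=0.0)
    module_sd: float = Field(1.5, gt=0.0)
    latent_sd: float = Field(1.5, gt=0.0)
    libsize_sigma: float = Field(0.15, ge=0.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        if abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise ValueError("stage_probs: must sum to 1 within 1e-9")
        if any(p < 0 for p in self.stage_probs):
            raise ValueError("stage_probs: entries must be nonnegative")
        if self.n_sponge_triplets > min(self.n_mrna, self.n_lncrna, self.n_mirna):
            raise ValueError(
                "n_sponge_triplets: exceeds min(n_mrna, n_lncrna, n_mirna)"
            )
        if any(m <= 0 for m in self.module_sizes):
            raise ValueError("module_sizes: all sizes must be positive")
        if sum(self.module_sizes) + self.n_sponge_triplets + self.n_lnm_informative > self.n_mrna:
            raise ValueError(
                "n_mrna: too small for module_sizes + sponge targets + LNM features"
            )
        return self


@dataclasses.dataclass
class GroundTruth:
    """What was planted, keyed by emitted feature ids."""

    sponge_triplets: list[tuple[str, str, str]]
    de_features: dict[str, int]          # feature -> +1 (up in tumor) / -1
    stage_features: set[str]
    lnm_features: set[str]
    module_membership: dict[str, str]    # feature -> module label


def _feature_names(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}_{i + 1:0{width}d}" for i in range(n)]


def generate_cohort(
    spec: CohortSpec,
    per_feature_dispersion: np.ndarray | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Draw one cohort; identical ``spec`` (incl. seed) gives identical output.

    Parameters
    ----------
    spec
        Validated cohort parameters.
    per_feature_dispersion
        Optional per-feature NB dispersion vector (length = total features,
        mRNA block first, then lncRNA, then miRNA); overrides the scalar
        ``spec.nb_dispersion``.
    """
    ss = np.random.SeedSequence(spec.seed)
    (ss_design, ss_means, ss_bio, ss_module, ss_sponge, ss_lib, ss_counts) = (
        np.random.default_rng(c) for c in ss.spawn(7)
    )

    n = spec.n_tumor + spec.n_normal
    samples = _feature_names("tumor", spec.n_tumor) + _feature_names(
        "normal", spec.n_normal
    )
    is_tumor = np.array([True] * spec.n_tumor + [False] * spec.n_normal)

    stage = np.array([""] * n, dtype=object)
    stage[is_tumor] = ss_design.choice(STAGES, size=spec.n_tumor, p=spec.stage_probs)
    lnm = np.zeros(n, dtype=bool)
    lnm[is_tumor] = ss_design.random(spec.n_tumor) < spec.lnm_rate

    meta = pd.DataFrame(
        {
            "group": np.where(is_tumor, "tumor", "normal"),
            "stage": [s if s else pd.NA for s in stage],
            "lnm": pd.array(
                [bool(v) if t else pd.NA for v, t in zip(lnm, is_tumor)],
                dtype="boolean",
            ),
        },
        index=pd.Index(samples, name="sample"),
    )

    mrna = _feature_names("mRNA", spec.n_mrna)
    lncrna = _feature_names("lncRNA", spec.n_lncrna)
    mirna = _feature_names("miR", spec.n_mirna)
    features = mrna + lncrna + mirna
    classes = pd.Series(
        ["mRNA"] * spec.n_mrna + ["lncRNA"] * spec.n_lncrna + ["miRNA"] * spec.n_mirna,
        index=features,
        name="class",
    )
    n_feat = len(features)

    # --- role assignment (disjoint mRNA pools keep the ground truth clean)
    mrna_pool = list(ss_design.permutation(mrna))
    module_members: dict[str, str] = {}
    for mi, size in enumerate(spec.module_sizes):
        label = f"module_{mi + 1}"
        for f in mrna_pool[:size]:
            module_members[f] = label
        mrna_pool = mrna_pool[size:]
    sponge_mrna = mrna_pool[: spec.n_sponge_triplets]
    mrna_pool = mrna_pool[spec.n_sponge_triplets:]
    lnm_standalone = mrna_pool[: spec.n_lnm_informative]

    lnc_pool = list(ss_design.permutation(lncrna))
    mir_pool = list(ss_design.permutation(mirna))
    sponge_lnc = lnc_pool[: spec.n_sponge_triplets]
    sponge_mir = mir_pool[: spec.n_sponge_triplets]
    triplets = list(zip(sponge_lnc, sponge_mir, sponge_mrna))

    stage_pool = [f for f in lnc_pool[spec.n_sponge_triplets:]]
    if len(stage_pool) < spec.n_stage_features:
        stage_pool = stage_pool + mrna_pool[spec.n_lnm_informative:]
    stage_features = set(stage_pool[: spec.n_stage_features])

    # DE features: a de_fraction slice of every class, with sponge members
    # forced in so planted triplets survive the DE restriction downstream.
    de_features: dict[str, int] = {}
    for cls_names in (mrna, lncrna, mirna):
        n_de = int(round(spec.de_fraction * len(cls_names)))
        chosen = list(ss_design.permutation(cls_names)[:n_de])
        for f in chosen:
            de_features[f] = int(ss_design.integers(0, 2)) * 2 - 1
    for f in (*sponge_lnc, *sponge_mir, *sponge_mrna):
        if f not in de_features:
            de_features[f] = int(ss_design.integers(0, 2)) * 2 - 1

    # --- latent log2 mean matrix
    idx = {f: i for i, f in enumerate(features)}
    base = ss_means.normal(spec.mean_log2_expr, spec.sd_log2_expr, size=n_feat)
    M = np.tile(base[:, None], (1, n))

    M += ss_bio.normal(0.0, spec.bio_noise_sd, size=(n_feat, n))

    rho = spec.within_module_cor
    for mi in range(len(spec.module_sizes)):
        label = f"module_{mi + 1}"
        factor = ss_module.normal(0.0, 1.0, size=n)
        factor[lnm] += spec.module_factor_lnm_shift
        members = [f for f, lab in module_members.items() if lab == label]
        for f in members:
            # coexpression blocks emulate adequately expressed genes, where
            # counting noise does not swamp the shared factor
            base[idx[f]] = max(base[idx[f]], spec.mean_log2_expr)
        eps = ss_module.normal(0.0, 1.0, size=(len(members), n))
        block = spec.module_sd * (np.sqrt(rho) * factor[None, :] + np.sqrt(1 - rho) * eps)
        rows = [idx[f] for f in members]
        # the shared factor replaces (not adds to) the generic noise
        M[rows, :] = base[rows][:, None] + block

    # Sponge triplets: lncRNA and miRNA get their own latent abundance axes
    # (candidate ceRNAs are kept well expressed); free miRNA is
    # f = m * (1 - strength * rank-scaled lncRNA) on the latent scale, and
    # the target mRNA mean is multiplied by exp(-k * f) with f in units of
    # its cohort mean, so k is the log-repression at the average free-miRNA
    # level. Tumor shifts are added afterwards, on top of the coupling, with
    # ceRNA-consistent directions (lncRNA and target together, miRNA
    # opposite) so the group contrast reinforces rather than scrambles the
    # sponge geometry.
    for lnc_f, mir_f, mrna_f in triplets:
        for f in (lnc_f, mir_f, mrna_f):
            base[idx[f]] = max(base[idx[f]], spec.mean_log2_expr)
        z_l = ss_sponge.normal(0.0, 1.0, size=n)
        z_m = ss_sponge.normal(0.0, 1.0, size=n)
        M[idx[lnc_f], :] = base[idx[lnc_f]] + spec.latent_sd * z_l
        M[idx[mir_f], :] = base[idx[mir_f]] + spec.latent_sd * z_m
        u = (np.argsort(np.argsort(z_l)) + 1) / (n + 1)          # rank-scaled
        m_abund = np.exp2(spec.latent_sd * z_m)
        free = m_abund * (1.0 - spec.sponge_strength * u)
        M[idx[mrna_f], :] = base[idx[mrna_f]] - spec.sponge_k * (
            free / free.mean()
        ) * np.log2(np.e)
        st = int(ss_design.integers(0, 2)) * 2 - 1
        de_features[lnc_f] = st
        de_features[mrna_f] = st
        de_features[mir_f] = -st

    for f, sign in de_features.items():
        M[idx[f], is_tumor] += sign * spec.de_log2fc
    for f in stage_features:
        M[idx[f], stage == "III"] += spec.stage_log2fc
        M[idx[f], stage == "IV"] += 2.0 * spec.stage_log2fc
    for f in lnm_standalone:
        M[idx[f], lnm] += spec.lnm_log2fc

    lib = np.exp(ss_lib.normal(0.0, spec.libsize_sigma, size=n))
    mu = lib[None, :] * np.exp2(M)
    disp = (
        np.asarray(per_feature_dispersion, dtype=float)
        if per_feature_dispersion is not None
        else np.full(n_feat, spec.nb_dispersion)
    )
    if disp.shape != (n_feat,):
        raise ValueError("per_feature_dispersion: wrong length")
    r = 1.0 / disp
    counts = ss_counts.negative_binomial(r[:, None], r[:, None] / (r[:, None] + mu))

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=pd.Index(features, name="feature"), columns=samples),
        classes,
    )
    truth = GroundTruth(
        sponge_triplets=triplets,
        de_features=de_features,
        stage_features=stage_features,
        lnm_features=set(lnm_standalone),
        module_membership=module_members,
    )
    return matrix, meta, truth


# ---------------------------------------------------------------------------
# interaction tables and drug rank profiles (stand-ins for the external
# prediction databases and the drug-perturbation compendium)
# ---------------------------------------------------------------------------

def generate_interaction_tables(
    truth: GroundTruth,
    matrix: ExpressionMatrix,
    n_decoy_triplets: int = 20,
    n_noise_pairs: int = 30,
    noise_keep_prob: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[pd.DataFrame]]:
    """Build a lncRNA-miRNA table plus three miRNA-mRNA prediction tables.

    Planted sponge triplets appear in all tables (so they survive the
    three-way intersection); ``n_decoy_triplets`` random triplets over
    differentially expressed features are likewise fully supported but carry
    no expression coupling; ``n_noise_pairs`` extra pairs land in a random
    subset of the target tables and are mostly removed by the intersection.
    """
    rng = np.random.default_rng(seed)
    classes = matrix.feature_class
    de = set(truth.de_features)

    def _de_pool(cls: str) -> list[str]:
        pool = [f for f in classes[classes == cls].index if f in de]
        return pool or list(classes[classes == cls].index)

    lnc_mir: list[tuple[str, str]] = []
    mir_mrna: list[tuple[str, str]] = []
    for lnc, mir, mr in truth.sponge_triplets:
        lnc_mir.append((lnc, mir))
        mir_mrna.append((mir, mr))

    planted = set(truth.sponge_triplets)
    planted_mrna = {t[2] for t in truth.sponge_triplets}
    lnc_pool, mir_pool = _de_pool("lncRNA"), _de_pool("miRNA")
    mrna_pool = [f for f in _de_pool("mRNA") if f not in planted_mrna]
    for _ in range(n_decoy_triplets):
        trip = (
            str(rng.choice(lnc_pool)),
            str(rng.choice(mir_pool)),
            str(rng.choice(mrna_pool)),
        )
        if trip in planted:
            continue
        lnc_mir.append((trip[0], trip[1]))
        mir_mrna.append((trip[1], trip[2]))

    tables = [list(mir_mrna) for _ in range(3)]
    all_lnc = list(classes[classes == "lncRNA"].index)
    all_mir = list(classes[classes == "miRNA"].index)
    all_mrna = list(classes[classes == "mRNA"].index)
    for _ in range(n_noise_pairs):
        lnc_mir.append((str(rng.choice(all_lnc)), str(rng.choice(all_mir))))
        pair = (str(rng.choice(all_mir)), str(rng.choice(all_mrna)))
        for t in tables:
            if rng.random() < noise_keep_prob:
                t.append(pair)

    lnc_mir_df = dedup_interactions(
        pd.DataFrame(lnc_mir, columns=["regulator", "target"]), "lncmir_synth"
    )
    target_dfs = [
        dedup_interactions(
            pd.DataFrame(t, columns=["regulator", "target"]), f"targets_synth_{lab}"
        )
        for t, lab in zip(tables, "ABC")
    ]
    return lnc_mir_df, target_dfs


def generate_drug_ranks(
    up: Sequence[str],
    down: Sequence[str],
    genes: Sequence[str],
    n_drugs: int = 50,
    n_reversing: int = 1,
    n_instances: int = 1,
    effect: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Drug x gene rank matrix with planted signature-reversing drugs.

    Each row is one perturbation instance (replicate instances share a drug
    id in the index); entries are ranks 1..n_genes, rank 1 = the gene most
    up-regulated by the drug. Reversing drugs push the query's ``down``
    genes to the top of their ranking and the ``up`` genes to the bottom,
    i.e. they invert the disease signature.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    gi = {g: j for j, g in enumerate(genes)}
    rows, index = [], []
    for d in range(n_drugs):
        reversing = d < n_reversing
        name = f"drug_rev_{d + 1}" if reversing else f"drug_{d + 1}"
        for _ in range(n_instances):
            score = rng.normal(0.0, 1.0, size=len(genes))
            if reversing:
                score[[gi[g] for g in down if g in gi]] += effect
                score[[gi[g] for g in up if g in gi]] -= effect
            order = np.argsort(-score, kind="stable")
            ranks = np.empty(len(genes), dtype=int)
            ranks[order] = np.arange(1, len(genes) + 1)
            rows.append(ranks)
            index.append(name)
    return pd.DataFrame(rows, index=pd.Index(index, name="drug"), columns=genes)


# ---------------------------------------------------------------------------
# fixture round-trip
# ---------------------------------------------------------------------------

_TRUTH_COLUMNS = ["record", "a", "b", "c"]


def write_fixture(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    truth: GroundTruth,
    directory: str | Path,
) -> list[Path]:
    """Write per-class matrices, metadata and the ground truth as TSV."""
    if not str(directory):
        raise ValueError("directory must be a non-empty path")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for cls, fname in (("mRNA", "mrna.tsv"), ("lncRNA", "lncrna.tsv"), ("miRNA", "mirna.tsv")):
        paths.append(write_expression_tsv(matrix.of_class(cls), directory / fname))
    paths.append(write_metadata_tsv(metadata, directory / "metadata.tsv"))

    records: list[tuple[str, str, str, str]] = []
    for lnc, mir, mr in truth.sponge_triplets:
        records.append(("triplet", lnc, mir, mr))
    for f, sign in sorted(truth.de_features.items()):
        records.append(("de", f, str(sign), ""))
    for f in sorted(truth.stage_features):
        records.append(("stage", f, "", ""))
    for f in sorted(truth.lnm_features):
        records.append(("lnm", f, "", ""))
    for f, lab in sorted(truth.module_membership.items()):
        records.append(("module", f, lab, ""))
    tdf = pd.DataFrame(records, columns=_TRUTH_COLUMNS)
    tpath = directory / "ground_truth.tsv"
    tdf.to_csv(tpath, sep="\t", index=False)
    paths.append(tpath)
    return paths


def read_fixture(directory: str | Path) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    directory = Path(directory)
    parts = [
        read_expression_tsv(directory / f)
        for f in ("mrna.tsv", "lncrna.tsv", "mirna.tsv")
    ]
    matrix = ExpressionMatrix(
        pd.concat([p.values for p in parts]),
        pd.concat([p.feature_class for p in parts]),
    )
    meta = read_metadata_tsv(directory / "metadata.tsv")
    tdf = pd.read_csv(directory / "ground_truth.tsv", sep="\t", dtype=str).fillna("")
    truth = GroundTruth([], {}, set(), set(), {})
    for _, row in tdf.iterrows():
        if row["record"] == "triplet":
            truth.sponge_triplets.append((row["a"], row["b"], row["c"]))
        elif row["record"] == "de":
            truth.de_features[row["a"]] = int(row["b"])
        elif row["record"] == "stage":
            truth.stage_features.add(row["a"])
        elif row["record"] == "lnm":
            truth.lnm_features.add(row["a"])
        elif row["record"] == "module":
            truth.module_membership[row["a"]] = row["b"]
    return matrix, meta, truth
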