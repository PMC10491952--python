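"""Synthetic gene/isoform expression datasets with planted structure.

The generator emulates the statistical assumptions the predictor relies on:

* paired matrices where each gene's expression row is the column-wise SUM of
  its isoforms' rows (TPM-like additivity);
* a planted subset of "informative" experiment columns on which
  function-carrying isoforms are shifted upward relative to the rest;
* SIG/MIG structure, with exactly one planted "responsible" isoform per
  positive MIG (its decoy siblings draw from the negative noise
  distribution, so the multiple-instance ground truth is well defined);
* an optional variance scaling of the isoform matrix emulating a
  gene-vs-isoform domain shift.

Everything is seed-deterministic.  The generator makes no attempt at
count-distribution realism (negative-binomial noise, library-size effects);
the predictor is scale-free after centering, so Gaussian noise suffices for
method-level testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import AnnotationTable, ExpressionMatrix, GeneIsoformMap

__all__ = ["SimConfig", "SimTruth", "generate", "write_dataset"]


@dataclass
class SimConfig:
    """Generator settings.

    effect_size is the mean shift of informative features for
    function-carrying isoforms, in units of noise_sd.  domain_shift
    multiplicatively scales the isoform matrix after the gene matrix is
    formed (1.0 = no shift).  isoforms_per_mig may be an int or an
    inclusive (lo, hi) range.
    """

    n_sig: int = 100
    n_mig: int = 50
    isoforms_per_mig: int | tuple[int, int] = 3
    n_features: int = 50
    n_informative: int = 10
    effect_size: float = 1.5
    noise_sd: float = 1.0
    positive_fraction: float = 0.3
    domain_shift: float = 1.0
    term_id: str = "GO:SYNTH"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sig < 1 or self.n_mig < 0 or self.n_features < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative must be in [0, n_features]")
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must be in (0, 1)")
        if self.noise_sd <= 0 or self.domain_shift <= 0:
            raise ValueError("noise_sd and domain_shift must be > 0")
        lo = self.isoforms_per_mig if isinstance(self.isoforms_per_mig, int) \
            else self.isoforms_per_mig[0]
        if self.n_mig > 0 and lo < 2:
            raise ValueError("MIGs need >= 2 isoforms")


@dataclass
class SimTruth:
    """Ground truth of a generated dataset."""

    informative_features: list[str]
    responsible_isoform: dict[str, str]   # positive MIG gene -> isoform
    positive_genes: list[str]
    labels: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": "informative_feature", "id": f, "value": ""}
            for f in self.informative_features
        ]
        rows += [
            {"kind": "responsible_isoform", "id": g, "value": iso}
            for g, iso in self.responsible_isoform.items()
        ]
        rows += [
            {"kind": "gene_label", "id": g, "value": str(v)}
            for g, v in self.labels.items()
        ]
        return pd.DataFrame(rows)


def generate(
    cfg: SimConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GeneIsoformMap, AnnotationTable, SimTruth]:
    """Generate one dataset.

    Positive genes are allocated stratified by class —
    round(positive_fraction * n_sig) positive SIGs and
    round(positive_fraction * n_mig) positive MIGs — so planted counts are
    exact.  Function-carrying isoforms (the isoform of every positive SIG
    and one responsible isoform per positive MIG) get +effect_size*noise_sd
    on the informative columns; all other entries are N(0, noise_sd) noise.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    n_pos_sig = round(cfg.positive_fraction * cfg.n_sig)
    n_pos_mig = round(cfg.positive_fraction * cfg.n_mig)
    if n_pos_sig == 0 and n_pos_mig == 0:
        raise ValueError("configuration yields no positive genes")
    if n_pos_sig == cfg.n_sig and n_pos_mig == cfg.n_mig:
        raise ValueError("configuration yields no negative genes")

    feat_ids = [f"exp{j + 1}" for j in range(cfg.n_features)]
    informative = sorted(
        rng.choice(cfg.n_features, size=cfg.n_informative, replace=False)
    )
    shift = np.zeros(cfg.n_features)
    shift[informative] = cfg.effect_size * cfg.noise_sd

    sig_genes = [f"gS{i + 1}" for i in range(cfg.n_sig)]
    mig_genes = [f"gM{i + 1}" for i in range(cfg.n_mig)]
    pos_sigs = set(rng.choice(sig_genes, size=n_pos_sig, replace=False))
    pos_migs = set(rng.choice(mig_genes, size=n_pos_mig, replace=False)) \
        if cfg.n_mig else set()

    def n_isos() -> int:
        if isinstance(cfg.isoforms_per_mig, int):
            return cfg.isoforms_per_mig
        lo, hi = cfg.isoforms_per_mig
        return int(rng.integers(lo, hi + 1))

    iso_ids: list[str] = []
    pairs: list[tuple[str, str]] = []
    carrier = []  # per isoform: does it carry the function?
    responsible: dict[str, str] = {}
    for g in sig_genes:
        iso = f"{g}.1"
        iso_ids.append(iso)
        pairs.append((g, iso))
        carrier.append(g in pos_sigs)
    for g in mig_genes:
        k = n_isos()
        isos = [f"{g}.{j + 1}" for j in range(k)]
        if g in pos_migs:
            resp = isos[int(rng.integers(k))]
            responsible[g] = resp
        else:
            resp = None
        for iso in isos:
            iso_ids.append(iso)
            pairs.append((g, iso))
            carrier.append(iso == resp)

    n_iso = len(iso_ids)
    Xiso = rng.normal(0.0, cfg.noise_sd, size=(n_iso, cfg.n_features))
    Xiso[np.asarray(carrier, bool)] += shift

    mapping = GeneIsoformMap.from_pairs(pairs)
    gene_ids = sig_genes + mig_genes
    iso_row = {t: i for i, t in enumerate(iso_ids)}
    Xg = np.vstack(
        [
            Xiso[[iso_row[t] for t in mapping.isoforms_of[g]]].sum(axis=0)
            for g in gene_ids
        ]
    )
    if cfg.domain_shift != 1.0:
        Xiso = Xiso * cfg.domain_shift

    positives = sorted(pos_sigs | pos_migs)
    annotations = AnnotationTable.from_pairs(
        [(g, cfg.term_id) for g in positives]
    )
    labels = {g: (1 if g in set(positives) else 0) for g in gene_ids}
    truth = SimTruth(
        informative_features=[feat_ids[j] for j in informative],
        responsible_isoform=responsible,
        positive_genes=positives,
        labels=labels,
    )
    return (
        ExpressionMatrix(gene_ids, feat_ids, Xg),
        ExpressionMatrix(iso_ids, feat_ids, Xiso),
        mapping,
        annotations,
        truth,
    )


def write_dataset(
    cfg: SimConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Generate and write the four input TSVs plus a truth TSV."""
    from .data_model import write_expression_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes, isos, mapping, annotations, truth = generate(cfg)
    paths = {
        "gene_expr": out / "gene_expression.tsv",
        "iso_expr": out / "isoform_expression.tsv",
        "map": out / "gene_isoform_map.tsv",
        "annotations": out / "annotations.tsv",
        "truth": out / "truth.tsv",
    }
    write_expression_matrix(genes, paths["gene_expr"])
    write_expression_matrix(isos, paths["iso_expr"])
    pd.DataFrame(
        [(g, t) for t, g in mapping.gene_of.items()],
        columns=["gene_id", "isoform_id"],
    ).to_csv(paths["map"], sep="\t", index=False, header=False)
    pd.DataFrame(
        [(g, term) for term, gs in annotations.genes_of_term.items()
         for g in sorted(gs)],
        columns=["gene_id", "term_id"],
    ).to_csv(paths["annotations"], sep="\t", index=False, header=False)
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths
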