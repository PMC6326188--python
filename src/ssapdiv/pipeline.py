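"""End-to-end orchestration: one homolog pair, or a cohort of pairs.

``run_pair`` chains the stages — ΔΔG → preference profiles (biophysics),
replicate simulation with σ calibration, per-site JS/RMSD permutation
comparison with FDR, and (when structures are given) contact rewiring —
into a single record; ``run_cohort`` aggregates records across pairs,
bins the fraction of significant sites by sequence divergence with
bootstrap confidence intervals, and contrasts rewired-contact fractions
between substituted and conserved sites with a rank-sum test.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import ranksums

from .biophysics import FitnessModelSpec, ddg_to_preferences
from .io_formats import AlignmentMap, DdgMatrix, StructureModel, ValidationError
from .profile_compare import compare_profiles
from .replicate_sim import ReplicateSimParams
from .structure_analysis import (build_contacts, compare_contacts,
                                 divergence_binned_summary, sequence_divergence,
                                 srmsd)

__all__ = ["PairAnalysisRecord", "CohortResult", "run_pair", "run_cohort"]

logger = logging.getLogger("ssapdiv")


@dataclass
class PairAnalysisRecord:
    """Summary of one pairwise homolog comparison."""

    pair_id: str
    sequence_divergence: float
    srmsd: float | None
    n_sites_compared: int
    n_significant: int
    fraction_significant: float
    mean_js: float
    model: str
    per_site_path: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CohortResult:
    records: pd.DataFrame
    binned: pd.DataFrame
    fr_records: pd.DataFrame | None = None
    fr_binned_by_class: dict[str, pd.DataFrame] | None = None
    fr_ranksum_p: float | None = None


def _results_frame(results) -> pd.DataFrame:
    return pd.DataFrame([{
        "site_a": r.site_pair[0], "site_b": r.site_pair[1],
        "js": r.js_point, "rmsd_within": r.rmsd_within,
        "rmsd_between": r.rmsd_between, "rmsd_corrected": r.rmsd_corrected,
        "p": r.p_value, "q": r.q_value, "significant": r.significant,
    } for r in results])


def run_pair(ddg_a: DdgMatrix, ddg_b: DdgMatrix, alignment: AlignmentMap,
             model: FitnessModelSpec | None = None, target_r: float = 0.60,
             alpha: float = 0.05, n_replicates: int = 6, seed: int = 0,
             pair_id: str = "pair", out_dir: str | Path | None = None,
             structure_a: StructureModel | None = None,
             structure_b: StructureModel | None = None,
             contact_dialect: str = "allatom_3p5",
             sim_params: ReplicateSimParams | None = None):
    """Analyze one homolog pair; returns (record, per-site results, contact
    comparison or None). Writes a per-site TSV when ``out_dir`` is given."""
    model = model or FitnessModelSpec()
    rng = np.random.default_rng(seed)
    logger.info("pair %s: model=%s target_r=%.2f alpha=%.2f n_replicates=%d seed=%d",
                pair_id, model.model, target_r, alpha, n_replicates, seed)
    profile_a = ddg_to_preferences(ddg_a, model)
    profile_b = ddg_to_preferences(ddg_b, model)
    results, summary = compare_profiles(
        profile_a, profile_b, alignment, target_r=target_r, alpha=alpha,
        sim_params=sim_params, n_replicates=n_replicates, rng=rng)
    seq_a = ddg_a.wildtype_sequence
    seq_b = ddg_b.wildtype_sequence
    divergence = (alignment.sequence_divergence
                  if alignment.sequence_divergence is not None
                  else sequence_divergence(alignment, seq_a, seq_b))
    try:
        deviation = srmsd(alignment)
    except ValidationError:
        deviation = None

    contacts = None
    if structure_a is not None and structure_b is not None:
        net_a = build_contacts(structure_a, contact_dialect)
        net_b = build_contacts(structure_b, contact_dialect)
        contacts = compare_contacts(net_a, net_b, alignment, seq_a, seq_b)

    per_site_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        per_site_path = str(out_dir / f"{pair_id}_sites.tsv")
        _results_frame(results).to_csv(per_site_path, sep="\t", index=False)

    record = PairAnalysisRecord(
        pair_id=pair_id,
        sequence_divergence=float(divergence),
        srmsd=deviation,
        n_sites_compared=summary["n_sites"],
        n_significant=summary["n_significant"],
        fraction_significant=summary["fraction_significant"],
        mean_js=summary["mean_js"],
        model=model.model,
        per_site_path=per_site_path,
    )
    return record, results, contacts


def run_cohort(pair_inputs: list[dict], bins=None, n_boot: int = 2000,
               seed: int = 0, min_coverage: float = 0.95,
               out_dir: str | Path | None = None) -> CohortResult:
    """Run ``run_pair`` over a list of keyword-argument dicts and aggregate.

    Pairs whose alignment covers less than ``min_coverage`` of either
    structure are skipped with a logged message, as are pairs that fail; the
    cohort continues. The binned table summarizes fraction-significant vs
    sequence divergence with bootstrap CIs; when structures are present,
    per-site rewired-contact fractions are split into substituted vs
    conserved sites and contrasted with a Wilcoxon rank-sum test.
    """
    rng = np.random.default_rng(seed)
    records: list[PairAnalysisRecord] = []
    fr_rows: list[dict] = []
    for k, kwargs in enumerate(pair_inputs):
        kwargs = dict(kwargs)
        kwargs.setdefault("pair_id", f"pair{k}")
        # per-pair seed derived from the pair id, so cohort order is irrelevant
        kwargs.setdefault("seed", (zlib.crc32(kwargs["pair_id"].encode()) ^ seed)
                          % (2**31 - 1))
        if out_dir is not None:
            kwargs.setdefault("out_dir", out_dir)
        aln: AlignmentMap = kwargs["alignment"]
        cov = [c for c in (aln.coverage_a, aln.coverage_b) if c is not None]
        if cov and min(cov) < min_coverage:
            logger.info("skipping %s: alignment coverage %.2f below %.2f",
                        kwargs["pair_id"], min(cov), min_coverage)
            continue
        try:
            record, _results, contacts = run_pair(**kwargs)
        except Exception:
            logger.exception("pair %s failed; skipping", kwargs["pair_id"])
            continue
        records.append(record)
        if contacts is not None:
            for sc in contacts.per_site:
                if sc.f_r is None:
                    continue
                fr_rows.append({
                    "pair_id": record.pair_id,
                    "divergence": record.sequence_divergence,
                    "site_a": sc.site_pair[0], "site_class": sc.site_class,
                    "f_r": sc.f_r,
                })
    if not records:
        raise ValidationError("cohort produced no analyzable pairs")
    rec_df = pd.DataFrame(sorted((r.to_dict() for r in records),
                                 key=lambda d: d["pair_id"]))
    binned = divergence_binned_summary(
        zip(rec_df["sequence_divergence"], rec_df["fraction_significant"]),
        bins=bins, n_boot=n_boot, rng=rng)
    fr_df = pd.DataFrame(fr_rows) if fr_rows else None
    fr_binned = None
    fr_p = None
    if fr_df is not None and not fr_df.empty:
        fr_binned = {
            cls: divergence_binned_summary(
                zip(sub["divergence"], sub["f_r"]), bins=bins, n_boot=n_boot,
                rng=rng)
            for cls, sub in fr_df.groupby("site_class")
        }
        sub = fr_df[fr_df.site_class == "substituted"]["f_r"]
        con = fr_df[fr_df.site_class == "conserved_aa"]["f_r"]
        if len(sub) and len(con):
            fr_p = float(ranksums(sub, con).pvalue)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rec_df.to_csv(out_dir / "cohort_records.tsv", sep="\t", index=False)
        binned.to_csv(out_dir / "cohort_binned.tsv", sep="\t", index=False)
        if fr_df is not None:
            fr_df.to_csv(out_dir / "cohort_fr.tsv", sep="\t", index=False)
    return CohortResult(rec_df, binned, fr_df, fr_binned, fr_p)
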