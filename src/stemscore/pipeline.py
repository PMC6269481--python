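"""End-to-end orchestration: score -> survive -> derive -> enrich, with a manifest.

A single YAML config names the inputs, the stages to run, one global seed and
an output directory.  Stages always execute in dependency order; each stage's
numeric outputs go to their own files (never interleaved with logging), and a
machine-readable run manifest — config echo, SHA-256 input digests, per-stage
outputs, seeds, package version — is written last, so the presence of
``manifest.json`` certifies a complete run.  Identical config + inputs +
seed reproduce every output byte for byte.

The global seed is split deterministically per stage (a fixed stage index is
mixed into a ``SeedSequence``), so re-running a single stage reproduces the
full-run result for that stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .derive import correlate_genes_with_score, derive_top_signature
from .enrichment import preranked_enrichment
from .io import (
    load_packaged_signature,
    read_clinical_table,
    read_expression_matrix,
    read_gmt,
    read_signature,
    write_signature,
)
from .scoring import dichotomize_by_median, signature_score
from .survival import (
    km_estimate,
    logrank_test,
    multivariate_logistic,
    restrict_outcome_subset,
    survival_at,
)

__all__ = ["PipelineError", "RunManifest", "run_pipeline", "stage_seed"]

log = logging.getLogger("stemscore")

STAGE_ORDER = ("score", "survive", "derive", "enrich")
_STAGE_INDEX = {"simulate": 0, "score": 1, "survive": 2, "derive": 3, "enrich": 4}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying error."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunManifest:
    config: dict
    input_digests: dict[str, str]
    seed: int
    stage_outputs: dict[str, list[str]]
    version: str

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "input_digests": self.input_digests,
            "seed": self.seed,
            "stage_outputs": self.stage_outputs,
            "version": self.version,
        }


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the single global seed."""
    ss = np.random.SeedSequence(entropy=[int(global_seed), _STAGE_INDEX[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_scores(scores, groups, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tscore\tgroup\n")
        labels = groups.label if groups is not None else [""] * len(scores)
        for sid, sc, lab in zip(scores.sample_ids, scores.score, labels):
            fh.write(f"{sid}\t{sc:.12g}\t{lab}\n")


def run_pipeline(config_path: str | Path) -> RunManifest:
    """Execute the configured stages; return (and write) the run manifest."""
    config_path = Path(config_path)
    with open(config_path, encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    out_dir = Path(config.get("out_dir", "stemscore_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    requested = config.get("stages", list(STAGE_ORDER))
    unknown = [s for s in requested if s not in STAGE_ORDER]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; choose from {list(STAGE_ORDER)}")
    deps = {"survive": {"score"}, "derive": {"score"}, "enrich": {"score", "derive"}}
    needed = set(requested)
    for s in requested:
        needed |= deps.get(s, set())
    stages = [s for s in STAGE_ORDER if s in needed]
    inputs = config.get("inputs", {})

    input_digests: dict[str, str] = {}
    for key, value in inputs.items():
        p = Path(value)
        if not p.exists():
            raise FileNotFoundError(f"input {key!r}: no such file {value!r}")
        input_digests[key] = _sha256(p)

    failed_marker = out_dir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    stage_outputs: dict[str, list[str]] = {}
    state: dict = {}

    def run_stage(name: str, fn) -> None:
        log.info("stage %s: starting", name)
        try:
            stage_outputs[name] = [str(p) for p in fn()]
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            failed_marker.write_text(f"{name}: {exc}\n", encoding="utf-8")
            raise PipelineError(name, exc) from exc
        log.info("stage %s: done", name)

    def stage_score() -> list[Path]:
        mat = read_expression_matrix(inputs["mirna_matrix"])
        sig = (
            read_signature(inputs["signature"])
            if "signature" in inputs
            else load_packaged_signature()
        )
        opts = config.get("score", {})
        scores = signature_score(mat, sig, min_coverage=opts.get("min_coverage", 0.5))
        groups = dichotomize_by_median(scores)
        state["scores"], state["groups"] = scores, groups
        out = out_dir / "scores.tsv"
        _write_scores(scores, groups, out)
        return [out]

    def stage_survive() -> list[Path]:
        clinical = read_clinical_table(inputs["clinical"])
        scores, groups = state["scores"], state["groups"]
        opts = config.get("survive", {})
        clin = clinical.data.set_index("sample_id").loc[list(scores.sample_ids)]
        times = clin["os_time"].to_numpy(dtype=float)
        events = clin["os_event"].to_numpy(dtype=int)
        labels = np.array(groups.label)
        result = logrank_test(times, events, labels)
        report: dict = {
            "logrank": {"chi2": result.chi2, "df": result.df, "p": result.p},
            "groups": {},
        }
        horizon = float(opts.get("survival_at_years", 5.0))
        for level in ("high", "low"):
            mask = labels == level
            curve = km_estimate(times[mask], events[mask])
            at = survival_at(curve, horizon)
            report["groups"][level] = {
                "n": int(mask.sum()),
                "events": int(events[mask].sum()),
                f"survival_at_{horizon:g}y": at.estimate,
                "ci": [at.ci_lower, at.ci_upper],
            }
        covariate_cols = [
            c for c in ("mycn_amplified", "stage4", "age_ge_1y") if clin[c].notna().any()
        ]
        if covariate_cols:
            outcome, kept = restrict_outcome_subset(
                read_clinical_table(inputs["clinical"]),
                min_followup=float(opts.get("min_followup", 3.0)),
            )
            kept_set = [s for s in kept if s in set(scores.sample_ids)]
            high = dict(zip(groups.sample_ids, groups.as_bool()))
            covs = clin.loc[kept_set, covariate_cols].astype("Float64").astype(float)
            covs["score_high"] = [float(high[s]) for s in kept_set]
            kept_outcome = dict(zip(kept, outcome))
            fit = multivariate_logistic(
                np.array([kept_outcome[s] for s in kept_set]), covs
            )
            report["logistic"] = {
                "n_used": fit.n_used,
                "n_excluded": fit.n_excluded,
                "converged": fit.converged,
                "separation": fit.separation,
                "terms": {
                    term: {
                        "odds_ratio": float(row["odds_ratio"]),
                        "p": float(row["p"]),
                    }
                    for term, row in fit.table.iterrows()
                },
            }
        out = out_dir / "survival_report.json"
        out.write_text(json.dumps(report, indent=2), encoding="utf-8")
        return [out]

    def stage_derive() -> list[Path]:
        mrna = read_expression_matrix(inputs["mrna_matrix"])
        opts = config.get("derive", {})
        ranked = correlate_genes_with_score(mrna, state["scores"])
        sig = derive_top_signature(ranked, n=int(opts.get("top_n", 500)))
        state["ranked"], state["mrna_signature"] = ranked, sig
        ranked_out = out_dir / "ranked_genes.tsv"
        ranked.to_frame().to_csv(ranked_out, sep="\t", index=False, float_format="%.12g")
        sig_out = out_dir / "mrna_signature.tsv"
        write_signature(sig, sig_out)
        return [ranked_out, sig_out]

    def stage_enrich() -> list[Path]:
        sets = read_gmt(inputs["gene_sets"])
        opts = config.get("enrich", {})
        report = preranked_enrichment(
            state["ranked"],
            sets,
            weight_exponent=float(opts.get("weight_exponent", 1.0)),
            n_perm=int(opts.get("n_perm", 1000)),
            seed=stage_seed(seed, "enrich"),
        )
        out = out_dir / "enrichment.tsv"
        with open(out, "w", encoding="utf-8") as fh:
            fh.write("set\tsize\tES\tNES\tp\tFDR\tleading_edge\n")
            for r in report:
                fh.write(
                    f"{r.set_name}\t{r.size}\t{r.es:.12g}\t{r.nes:.12g}\t"
                    f"{r.p_perm:.12g}\t{r.fdr_q:.12g}\t{','.join(r.leading_edge)}\n"
                )
        return [out]

    fns = {
        "score": stage_score,
        "survive": stage_survive,
        "derive": stage_derive,
        "enrich": stage_enrich,
    }
    for name in stages:
        run_stage(name, fns[name])

    manifest = RunManifest(
        config=config,
        input_digests=input_digests,
        seed=seed,
        stage_outputs=stage_outputs,
        version=__version__,
    )
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=2), encoding="utf-8"
    )
    return manifest
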