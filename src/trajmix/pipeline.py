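"""End-to-end orchestration: read -> QC -> z-score -> sweep -> select ->
classify -> profiles -> discriminant regions -> association.

Every stochastic stage draws its seed deterministically from the master
seed, so two runs with the same configuration produce bit-identical
artifacts. Each stage writes its artifact into the output directory and a
log line with an ISO timestamp, the seed and input hashes. A rerun over an
existing output directory with an unchanged configuration reuses the cached
sweep table and refit chains instead of refitting.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .associate import fit_multioutput_model
from .cohort import apply_qc, read_cohort, zscore_regions
from .discriminate import fit_shrinkage_logits, rank_regions
from .mixmodel import McmcConfig, PosteriorChains, fit_mixture, relabel_chains
from .profiles import fitted_profiles, mds_embedding, trajectory_heat_table
from .select import (
    baseline_initializers,
    classify_subjects,
    derive_seed,
    order_clusters,
    run_sweep,
    select_model,
    sweep_table,
)


@dataclass
class PipelineConfig:
    cohort_path: str
    manifest_path: str
    out_dir: str
    min_visits: int = 2
    fa_floor: float = 0.25
    max_missing_frac: float = 0.2
    skip_qc: bool = False  # for cohorts already on the Z scale
    Ks: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    n_iter: int = 5000
    burn_in_frac: float = 0.5
    thin: int = 5
    master_seed: int = 0
    force_k: int | None = None
    hpd_level: float = 0.95
    pair_threshold: float = 0.60
    strong_threshold: float = 0.90
    min_models: int = 2
    discriminant_iter: int = 2000
    association_iter: int = 2000
    biomarkers: tuple[str, ...] = ()
    ages: tuple[float, ...] = (60.0, 75.0, 90.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.hpd_level < 1.0:
            raise ValueError("hpd_level must lie in (0, 1)")
        for name in ("pair_threshold", "strong_threshold"):
            v = getattr(self, name)
            if not 0.5 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0.5, 1]")
        if self.min_visits < 1 or self.n_iter < 1:
            raise ValueError("counts must be positive")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["Ks"] = list(self.Ks)
        d["biomarkers"] = list(self.biomarkers)
        d["ages"] = list(self.ages)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("Ks", "biomarkers", "ages"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        for p in (self.cohort_path, self.manifest_path):
            with open(p, "rb") as fh:
                blob += hashlib.sha256(fh.read()).digest()
        return hashlib.sha256(blob).hexdigest()[:16]


class _Log:
    def __init__(self, path: Path):
        self.path = path

    def line(self, stage: str, msg: str) -> None:
        stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        with open(self.path, "a") as fh:
            fh.write(f"{stamp} [{stage}] {msg}\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the output directory.

    Any stage failure raises with the stage name so a partial run is easy to
    locate; completed artifacts stay on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "pipeline.log")
    chash = config.content_hash()
    config.to_yaml(out / "config.yaml")
    state_path = out / "state.json"
    cached = (
        state_path.exists()
        and json.loads(state_path.read_text()).get("config_hash") == chash
    )

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            log.line(name, f"FAILED: {exc}")
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log.line(name, f"done in {time.perf_counter() - t0:.2f}s")
        return result

    log.line("start", f"config hash {chash} seed {config.master_seed}")

    cohort = stage("read", lambda: read_cohort(config.cohort_path, config.manifest_path))
    if config.skip_qc:
        qc_cohort = cohort
    else:
        def _qc():
            c, report = apply_qc(
                cohort, config.min_visits, config.fa_floor, config.max_missing_frac
            )
            report.to_json(out / "qc.json")
            return c

        qc_cohort = stage("qc", _qc)
    zc = stage("zscore", lambda: zscore_regions(qc_cohort))

    mcmc = McmcConfig(
        n_iter=config.n_iter,
        burn_in_frac=config.burn_in_frac,
        thin=config.thin,
        store_trajectories=False,
    )

    sweep_csv = out / "sweep.csv"
    if cached and sweep_csv.exists():
        summaries = None
        table_df = pd.read_csv(sweep_csv)
        log.line("sweep", "reused cached sweep.csv")
    else:
        summaries = stage(
            "sweep",
            lambda: run_sweep(
                zc,
                Ks=config.Ks,
                mcmc=mcmc,
                master_seed=config.master_seed,
                hpd_level=config.hpd_level,
            ),
        )
        table_df = sweep_table(summaries)
        table_df.to_csv(sweep_csv, index=False)

    def _select():
        ok = table_df[table_df["status"] == "ok"]
        if ok.empty:
            raise ValueError("no successful fits in sweep")
        if config.force_k is not None:
            sub = ok[ok["K"] == config.force_k]
            if sub.empty:
                raise ValueError(f"no successful fit with forced K={config.force_k}")
            row = sub.loc[sub["deviance"].idxmin()]
            ranked = ok.copy()
        else:
            if summaries is not None:
                ranked, chosen = select_model(summaries)
                row = table_df[
                    (table_df["K"] == chosen.K) & (table_df["init_id"] == chosen.init_id)
                ].iloc[0]
            else:  # re-derive selection from the cached table
                from .select import ModelFitSummary

                summ = [
                    ModelFitSummary(
                        K=int(r.K),
                        init_id=int(r.init_id),
                        deviance=float(r.deviance),
                        poor_mix_frac=float(r.poor_mix_frac),
                        n_uncertain=int(r.n_uncertain),
                        seed=int(r.seed),
                        status=r.status,
                    )
                    for r in table_df.itertuples()
                ]
                ranked, chosen = select_model(summ)
                row = table_df[
                    (table_df["K"] == chosen.K) & (table_df["init_id"] == chosen.init_id)
                ].iloc[0]
        ranked.to_csv(out / "ranked_models.csv", index=False)
        with open(out / "chosen.json", "w") as fh:
            json.dump(
                {
                    "K": int(row["K"]),
                    "init_id": int(row["init_id"]),
                    "deviance": float(row["deviance"]),
                    "seed": int(row["seed"]),
                    "forced": config.force_k is not None,
                    "note": (
                        "Selection is advisory: a low-K solution may score best "
                        "by splitting high from low FA only; review ranked_models.csv."
                    ),
                },
                fh,
                indent=1,
            )
        return int(row["K"]), int(row["init_id"])

    K, init_id = stage("select", _select)

    chains_npz = out / "chains.npz"

    def _refit():
        if cached and chains_npz.exists():
            log.line("refit", "reused cached chains.npz")
            return PosteriorChains.load(chains_npz)
        inits = baseline_initializers(zc, K, seed=derive_seed(config.master_seed, K, 0))
        cfg = McmcConfig(
            n_iter=config.n_iter,
            burn_in_frac=config.burn_in_frac,
            thin=config.thin,
            seed=derive_seed(config.master_seed, K, init_id),
            store_trajectories=False,
        )
        ch = relabel_chains(fit_mixture(zc, K, inits[init_id - 1], cfg))
        ch = order_clusters(ch)
        ch.save(chains_npz)
        return ch

    chains = stage("refit", _refit)

    def _classify():
        labels = classify_subjects(chains, config.hpd_level)
        probs = chains.allocation_means()
        df = pd.DataFrame(probs, columns=[f"p_cluster_{k+1}" for k in range(chains.K)])
        df.insert(0, "subject_id", chains.subject_ids)
        df["label"] = [str(lab) for lab in labels]
        df.to_csv(out / "labels.csv", index=False)
        return labels

    labels = stage("classify", _classify)

    def _profiles():
        prof = fitted_profiles(chains, ages=config.ages)
        frames = []
        for age, f in prof.fitted.items():
            f2 = f.copy()
            f2.insert(0, "age", age)
            frames.append(f2)
        pd.concat(frames).to_csv(out / "profiles.csv")
        heat = trajectory_heat_table(chains)
        heat.intercept.to_csv(out / "heat_intercept.csv")
        heat.slope.to_csv(out / "heat_slope.csv")
        emb = mds_embedding(chains.allocation_means())
        edf = pd.DataFrame(emb.coords, columns=["mds1", "mds2", "mds3"])
        edf.insert(0, "subject_id", chains.subject_ids)
        edf.to_csv(out / "embedding.csv", index=False)

    stage("profiles", _profiles)

    def _discriminate():
        report = fit_shrinkage_logits(
            zc,
            labels,
            n_iter=config.discriminant_iter,
            seed=derive_seed(config.master_seed, K, 99),
        )
        q = report.q_table()
        final = rank_regions(
            report,
            pair_threshold=config.pair_threshold,
            strong_threshold=config.strong_threshold,
            min_models=config.min_models,
        )
        q["selected"] = q["region"].isin(final)
        q.to_csv(out / "discriminant.csv", index=False)
        with open(out / "discriminant_regions.json", "w") as fh:
            json.dump(final, fh)
        return final

    final_regions = stage("discriminate", _discriminate)

    def _associate():
        regions = final_regions or zc.manifest.region_ids[:1]
        rep = fit_multioutput_model(
            zc,
            labels,
            regions,
            n_iter=config.association_iter,
            seed=derive_seed(config.master_seed, K, 101),
            biomarkers=config.biomarkers,
        )
        rep.coef.to_csv(out / "association.csv")
        rep.flag.to_csv(out / "association_flags.csv")

    stage("associate", _associate)

    state_path.write_text(json.dumps({"config_hash": chash}))
    log.line("end", "pipeline complete")
    return out


# ---------------------------------------------------------------------------
# Report


_SECTIONS = (
    ("Ranked models", "ranked_models.csv"),
    ("Cluster demographics", "labels.csv"),
    ("Trajectory heat tables", "heat_intercept.csv"),
    ("Allocation embedding", "embedding.csv"),
    ("Discriminant regions", "discriminant.csv"),
    ("Association matrix", "association.csv"),
)


def write_report(output_dir) -> Path:
    """Render a markdown summary of the pipeline artifacts; a missing
    artifact produces a gap notice instead of a failure."""
    out = Path(output_dir)
    lines = ["# Trajectory clustering report", ""]
    for title, fname in _SECTIONS:
        lines.append(f"## {title}")
        path = out / fname
        if not path.exists():
            lines.append(f"_Missing artifact: {fname}_")
            lines.append("")
            continue
        df = pd.read_csv(path)
        if fname == "labels.csv":
            counts = df["label"].value_counts().sort_index()
            lines.append(counts.to_frame("n_subjects").to_string())
        elif fname == "discriminant.csv":
            sel = df[df["selected"]]["region"].unique()
            lines.append(f"Selected regions: {', '.join(sel) if len(sel) else 'none'}")
            lines.append("")
            lines.append(df.head(20).to_string(index=False))
        else:
            lines.append(df.head(20).to_string(index=False))
        lines.append("")
    report = out / "report.md"
    report.write_text("\n".join(lines))
    return report
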