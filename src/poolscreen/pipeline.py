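"""End-to-end reproducible runs: simulate -> decode -> phenotype -> fit.

`run_simulate_decode` exercises the genotyping half (generator ->
decoder -> summary) and scores it against the generator's ground
truth.  `run_full` additionally simulates replicate chloramphenicol
chases for the decoded traps, joins phenotypes to genotypes by trap
id, fits maturation times per FP and replicate, and reports recovery
against the true kinetic parameters.

A single ``RunConfig`` governs a run; the same global seed always
yields byte-identical outputs.  Output CSVs carry a comment header
naming units and the configuration hash.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codebook import Codebook, CodebookSpec, build_codebook
from .decoding import (
    CAT_DECODED,
    DecodeParams,
    TrapDecode,
    decode_signal_table,
    summarize_experiment,
)
from .maturation import average_traces, choose_model, fit_maturation, summarize_fps
from .outliers import OutlierParams
from .phenotype import aggregate_lineages, bleed_filter, filter_lineages
from .synthetic import (
    CATEGORY_NORMAL,
    GenotypingGroundTruth,
    GenotypingSimConfig,
    PhenoSimConfig,
    StrainKinetics,
    gen_genotyping,
    gen_phenotyping,
)

__all__ = [
    "RunConfig",
    "run_simulate_decode",
    "run_full",
    "write_csv",
    "plot_recovery",
]


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible end-to-end run needs.

    ``seed`` propagates to every stochastic stage (codebook
    construction, both generators, per-replicate sub-seeds are derived
    from it deterministically).
    """

    genotyping: GenotypingSimConfig = field(default_factory=GenotypingSimConfig)
    strains: tuple[StrainKinetics, ...] = ()
    decode: DecodeParams | None = None
    outliers: OutlierParams = field(default_factory=OutlierParams)
    n_replicates: int = 3
    n_lineages_per_strain: int = 6
    noise_sd: float = 2.0
    bleed_fraction: float = 0.0
    t_acq: float = 300.0
    bleach_threshold: float = 0.85
    min_traps: int = 5
    min_lineages: int = 6
    seed: int = 0

    def hash(self) -> str:
        return hashlib.sha1(repr(self).encode()).hexdigest()[:12]


def _sub_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def write_csv(df: pd.DataFrame, path: str | Path, config_hash: str, units: str) -> None:
    """Write a CSV preceded by a comment header naming units and the
    configuration hash."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash} units: {units}\n")
        df.to_csv(fh, index=False)


@dataclass
class SimulateDecodeResult:
    codebook: Codebook
    decodes: list[TrapDecode]
    summary: pd.Series
    ground_truth: GenotypingGroundTruth
    confusion: pd.Series


def run_simulate_decode(config: RunConfig) -> SimulateDecodeResult:
    """Generate genotyping signals, decode them and score vs truth.

    The confusion summary scores occupied signal-producing ("normal")
    traps: fractions decoded correctly, decoded to the wrong barcode,
    and unassigned, plus exact category counts for the no-signal and
    double-signal constructions.
    """
    geno = config.genotyping
    cb = build_codebook(
        CodebookSpec(
            n_codes=geno.n_barcodes,
            n_rounds=geno.n_rounds,
            n_colors=geno.n_colors,
            seed=_sub_seed(config.seed, "codebook"),
        )
    )
    sim_cfg = GenotypingSimConfig(
        **{**geno.__dict__, "seed": _sub_seed(config.seed, "genotyping")}
    )
    signals, gt = gen_genotyping(sim_cfg, codebook=cb, mode="table")
    params = config.decode or DecodeParams(n_rounds=geno.n_rounds, n_channels=geno.n_colors)
    decodes = decode_signal_table(signals, cb, params)
    summary = summarize_experiment(decodes)

    truth = gt.traps.set_index("trap_id")
    normal = truth[truth.category == CATEGORY_NORMAL]
    by_trap = {d.trap_id: d for d in decodes}
    n_correct = n_wrong = n_unassigned = 0
    for trap_id, row in normal.iterrows():
        d = by_trap.get(trap_id)
        if d is None:
            continue
        if d.category == CAT_DECODED:
            if d.barcode_id == row.barcode_id:
                n_correct += 1
            else:
                n_wrong += 1
        else:
            n_unassigned += 1
    n_norm = len(normal)
    confusion = pd.Series(
        {
            "n_normal": n_norm,
            "frac_correct": n_correct / n_norm if n_norm else float("nan"),
            "frac_wrong": n_wrong / n_norm if n_norm else float("nan"),
            "frac_unassigned": n_unassigned / n_norm if n_norm else float("nan"),
        }
    )
    return SimulateDecodeResult(cb, decodes, summary, gt, confusion)


@dataclass
class FullRunResult:
    decode_result: SimulateDecodeResult
    replicate_fits: pd.DataFrame
    fp_summary: pd.DataFrame
    recovery: pd.DataFrame
    join_diagnostics: pd.Series


def run_full(config: RunConfig) -> FullRunResult:
    """Genotyping + replicate phenotyping joined by trap id.

    Strain i carries barcode i of the codebook.  For each replicate a
    fresh genotyping chip and chase are simulated; lineages are grouped
    by their trap's *decoded* barcode (as in a real screen, so decoding
    errors propagate), averaged, model-selected, and fitted.  The
    recovery table compares the per-FP mean fitted maturation time to
    the generator's true tau_m.
    """
    if not config.strains:
        raise ValueError("run_full needs at least one strain")
    if len(config.strains) > config.genotyping.n_barcodes:
        raise ValueError("more strains than barcodes")
    rep_rows = []
    decode_res = None
    join_missing_pheno = 0
    for rep in range(config.n_replicates):
        rep_cfg = RunConfig(
            **{
                **config.__dict__,
                "seed": _sub_seed(config.seed, f"replicate{rep}"),
            }
        )
        res = run_simulate_decode(rep_cfg)
        if decode_res is None:
            decode_res = res
        truth = res.ground_truth.traps
        fp_of_barcode = {
            res.codebook.ids[i]: s.fp_id for i, s in enumerate(config.strains)
        }
        # lineages live in occupied normal traps, at their TRUE genotype
        normal = truth[(truth.category == CATEGORY_NORMAL)]
        trap_ids = {
            s.fp_id: normal.loc[
                normal.barcode_id == res.codebook.ids[i], "trap_id"
            ].tolist()
            for i, s in enumerate(config.strains)
        }
        trap_ids = {k: v for k, v in trap_ids.items() if v}
        strains_present = tuple(s for s in config.strains if s.fp_id in trap_ids)
        if not strains_present:
            continue
        pheno_cfg = PhenoSimConfig(
            strains=strains_present,
            n_lineages_per_strain=config.n_lineages_per_strain,
            noise_sd=config.noise_sd,
            bleed_fraction=config.bleed_fraction,
            seed=_sub_seed(config.seed, f"pheno{rep}"),
        )
        cells, pheno_gt = gen_phenotyping(pheno_cfg, trap_ids=trap_ids)
        traces = aggregate_lineages(cells)
        traces = [t for t in filter_lineages(traces) if bleed_filter(t)]
        # join: group lineages by the DECODED barcode of their trap
        decoded_fp = {
            d.trap_id: fp_of_barcode.get(d.barcode_id)
            for d in res.decodes
            if d.category == CAT_DECODED
        }
        groups: dict[str, list] = {}
        n_traps_of: dict[str, set] = {}
        for t in traces:
            fp = decoded_fp.get(t.trap_id)
            if fp is None:
                join_missing_pheno += 1
                continue
            groups.setdefault(fp, []).append(t)
            n_traps_of.setdefault(fp, set()).add(t.trap_id)
        for fp, ts in groups.items():
            post = [t.post_chl() for t in ts]
            kind = choose_model(post, bleach_threshold=config.bleach_threshold)
            t_avg, f_avg = average_traces(post)
            fit = fit_maturation(t_avg, f_avg, kind=kind, t_acq=config.t_acq)
            rep_rows.append(
                {
                    "fp_id": fp,
                    "replicate": rep,
                    "tau_m": fit.tau_m,
                    "censored": fit.censored,
                    "kind": kind,
                    "success": fit.success,
                    "n_traps": len(n_traps_of[fp]),
                    "n_lineages": len(ts),
                }
            )
    replicate_fits = pd.DataFrame(rep_rows)
    fp_summary = summarize_fps(
        replicate_fits,
        min_traps=config.min_traps,
        min_lineages=config.min_lineages,
        t_acq=config.t_acq,
    )
    true_tau = {s.fp_id: s.tau_m for s in config.strains}
    rec_rows = []
    for _, row in fp_summary.iterrows():
        tt = true_tau[row.fp_id]
        rec_rows.append(
            {
                "fp_id": row.fp_id,
                "true_tau_m": tt,
                "mean_tau_m": row.mean_tau_m,
                "sem_tau_m": row.sem_tau_m,
                "rel_error": abs(row.mean_tau_m - tt) / tt,
                "n_replicates": row.n_replicates,
            }
        )
    recovery = pd.DataFrame(rec_rows)
    join = pd.Series(
        {
            "n_lineages_without_decoded_trap": join_missing_pheno,
            "n_fp_reported": len(fp_summary),
        }
    )
    return FullRunResult(decode_res, replicate_fits, fp_summary, recovery, join)


def plot_recovery(result: FullRunResult, path: str | Path) -> None:
    """Bar chart of per-FP mean fitted maturation time (with SEM error
    bars where three replicates qualify) against the generator truth."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rec = result.recovery.sort_values("true_tau_m")
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(rec)), 3.5))
    x = np.arange(len(rec))
    sem = rec.sem_tau_m.fillna(0.0)
    ax.bar(x, rec.mean_tau_m, yerr=sem, color="steelblue", label="fitted mean")
    ax.plot(x, rec.true_tau_m, "k_", markersize=14, label="true")
    ax.set_xticks(x)
    ax.set_xticklabels(rec.fp_id, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("maturation time (min)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
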