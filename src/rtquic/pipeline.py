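"""End-to-end orchestration: traces + plate map -> calls -> statistics -> report.

Runs are deterministic given their inputs and configuration; reports carry a
schema version, the configuration echo and the seed so any run can be
reproduced from its own report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .diagnostics import (
    Table2x2,
    build_unpaired_table,
    cohens_kappa,
    cramers_v,
    fisher_exact_two_sided,
    mcnemar_exact,
    proportion_summary,
)
from .kinetics import CallingConfig, RunResult, process_run
from .trace_io import (
    annotate_traces,
    read_plate_map,
    read_trace_csv,
    write_calls_csv,
)

__all__ = ["run_calling", "run_stats", "stats_from_counts", "stats_from_paired_table"]

logger = logging.getLogger("rtquic")

REPORT_SCHEMA_VERSION = 1


def _config_echo(config: CallingConfig) -> dict:
    d = dataclasses.asdict(config)
    d["noise_window"] = list(d["noise_window"])
    return d


def _config_hash(config: CallingConfig) -> str:
    blob = json.dumps(_config_echo(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _calls_frame(result: RunResult) -> pd.DataFrame:
    rows = []
    for c in result.calls:
        rows.append({
            "sample": c.sample_id, "subject": c.subject_id,
            "specimen": c.specimen.name, "diagnosis": c.diagnosis.name,
            "n_replicates": c.n_replicates,
            "n_positive_replicates": c.n_positive_replicates,
            "call": c.call,
            "lag_times": ";".join(format(x, ".6g") for x in c.lag_times),
            "endpoint_mean_percent": c.endpoint_mean_percent,
        })
    return pd.DataFrame(rows)


def run_calling(
    trace_csv,
    platemap_csv,
    config: CallingConfig = CallingConfig(),
    out_dir=None,
    dialect: str = "long",
    ignore_unmapped: bool = False,
    seed: int | None = None,
) -> tuple[RunResult, dict]:
    """Read, normalize, threshold and call one run; optionally write artefacts.

    Returns the :class:`RunResult` and the report dict. With ``out_dir`` set,
    writes ``calls.csv``, ``report.json`` and ``summary.txt`` there.
    """
    traces = read_trace_csv(trace_csv, dialect=dialect)
    plate_map = read_plate_map(platemap_csv)
    traces = annotate_traces(traces, plate_map, ignore_unmapped=ignore_unmapped)
    logger.info("calling %d traces / %d samples", len(traces),
                len({t.sample_id for t in traces}))
    result = process_run(traces, plate_map, config)
    logger.info("noise threshold %.4s%%, effective threshold %.4s%%",
                str(result.noise_threshold), str(result.effective_threshold))

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "software_version": __version__,
        "seed": seed,
        "config": _config_echo(config),
        "config_hash": _config_hash(config),
        "noise_threshold_percent": result.noise_threshold,
        "effective_threshold_percent": result.effective_threshold,
        "normalization_max_rfu": result.normalization_max,
        "baseline_windows": {
            ns.sample_id: {"t_start": ns.baseline_window[0],
                           "t_end": ns.baseline_window[1],
                           "baseline_rfu": ns.baseline_value,
                           "flags": list(ns.flags)}
            for ns in result.normalized
        },
        "calls": _calls_frame(result).to_dict(orient="records"),
        "warnings": sorted({f for c in result.calls for f in c.flags}),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_calls_csv(list(result.calls), out_dir / "calls.csv")
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        n_pos = sum(c.positive for c in result.calls)
        (out_dir / "summary.txt").write_text(
            f"samples: {len(result.calls)}\npositive: {n_pos}\n"
            f"effective threshold: {result.effective_threshold:.3f}%\n")
    return result, report


def _accuracy_dict(k: int, n: int) -> dict:
    s = proportion_summary(k, n)
    return {"n_positive": s.n_positive, "n_total": s.n_total,
            "estimate": s.estimate, "ci_low": s.ci_low, "ci_high": s.ci_high,
            "percent": s.percent_rounded}


def stats_from_counts(counts: pd.DataFrame) -> dict:
    """Statistics from a bare counts table (columns group, positive, total).

    Per-group exact proportion summaries always; Fisher's exact test and
    Cramér's V when exactly two groups are supplied.
    """
    for col in ("group", "positive", "total"):
        if col not in counts.columns:
            raise ValueError(f"counts table missing column {col!r}")
    out: dict = {"groups": {}}
    for _, row in counts.iterrows():
        out["groups"][str(row["group"])] = _accuracy_dict(int(row["positive"]),
                                                          int(row["total"]))
    if len(counts) == 2:
        r = counts.iloc
        table = Table2x2(int(r[0]["positive"]), int(r[0]["total"] - r[0]["positive"]),
                         int(r[1]["positive"]), int(r[1]["total"] - r[1]["positive"]))
        out["table"] = {"a": table.a, "b": table.b, "c": table.c, "d": table.d}
        out["fisher_p"] = fisher_exact_two_sided(table)
        try:
            out["cramers_v"] = cramers_v(table)
        except ValueError as e:
            out["cramers_v"] = None
            out["cramers_v_flag"] = str(e)
    return out


def stats_from_paired_table(table: Table2x2) -> dict:
    """Exact McNemar + Cohen's kappa block for a paired concordance table."""
    agr = cohens_kappa(table)
    return {
        "table": {"both_positive": table.a, "test1_only": table.b,
                  "test2_only": table.c, "both_negative": table.d},
        "kappa": agr.kappa, "kappa_se": agr.se_kappa,
        "kappa_ci": [agr.ci_low, agr.ci_high],
        "mcnemar_p": agr.mcnemar_p, "n_discordant": agr.n_discordant,
        "flags": list(agr.flags),
    }


def run_stats(
    counts_csv=None,
    calls_csv=None,
    paired_table: Table2x2 | None = None,
    out_json=None,
) -> dict:
    """Compute every statistic applicable to the supplied structure.

    Accepts a counts CSV (``group,positive,total``) and/or a calls CSV; a
    paired table adds the McNemar/kappa agreement block.
    """
    if counts_csv is None and calls_csv is None and paired_table is None:
        raise ValueError("supply a counts CSV, a calls CSV, or a paired table")
    stats: dict = {"schema_version": REPORT_SCHEMA_VERSION,
                   "software_version": __version__}
    if counts_csv is not None:
        stats["counts"] = stats_from_counts(pd.read_csv(counts_csv))
    if calls_csv is not None:
        from .trace_io import read_calls_csv

        calls = read_calls_csv(calls_csv)
        by_group = (calls.assign(positive=calls["call"] == "positive")
                    .groupby(["specimen", "diagnosis"])["positive"]
                    .agg(["sum", "count"]))
        stats["calls"] = {
            f"{spec}/{diag}": _accuracy_dict(int(s), int(n))
            for (spec, diag), (s, n) in by_group.iterrows()
        }
        specs = calls["specimen"].unique()
        pd_calls = calls[calls["diagnosis"] == "PD"]
        if len(specs) == 2 and not pd_calls.empty and \
                set(pd_calls["specimen"].unique()) == set(specs):
            table = build_unpaired_table(pd_calls, "specimen", sorted(specs))
            stats["specimen_comparison_pd"] = {
                "table": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
                "fisher_p": fisher_exact_two_sided(table),
                "cramers_v": cramers_v(table)
                if min(table.a + table.c, table.b + table.d) > 0 else None,
            }
    if paired_table is not None:
        stats["paired_agreement"] = stats_from_paired_table(paired_table)
    if out_json is not None:
        Path(out_json).write_text(json.dumps(stats, indent=2, sort_keys=True) + "\n")
    return stats
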