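"""CSV/JSON readers and writers plus text report rendering.

CSV dialect: comma-separated, dot decimal, UTF-8, ``# key=value`` metadata
header lines.  Units are load-bearing and must be present in the metadata.

* trace series — one file with repeated sections, each introduced by its own
  metadata block (``# receptor_uM=``, ``# ligand_uM=``, ...) and a
  ``time_s,signal`` column header;
* decay histograms — ``time_ns,counts`` (optionally ``irf_counts``);
* titrations — ``titrant_conc,response`` with titrant unit and probe
  concentration in the metadata.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np

from .decay import DecayFit, DecayHistogram
from .errors import InputError
from .kinetics import ReactionScheme
from .stopped_flow import (
    GlobalFitResult,
    ModelComparisonTable,
    PseudoFirstOrderResult,
    StoppedFlowTrace,
    TraceSeries,
)
from .titration import HillFit, TitrationCurve

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Low-level CSV plumbing
# ---------------------------------------------------------------------------

def _parse_number(token: str, path: str, lineno: int) -> float:
    token = token.strip()
    if "," in token:
        raise InputError(
            f"{path}:{lineno}: mixed decimal separators are not supported "
            f"(found comma inside numeric field {token!r})"
        )
    try:
        return float(token)
    except ValueError:
        raise InputError(f"{path}:{lineno}: cannot parse number {token!r}") from None


def _split_sections(path: Path) -> list[tuple[dict[str, str], list[str], list[tuple[int, list[str]]]]]:
    """Split a metadata-sectioned CSV into (metadata, columns, numbered rows)."""
    sections = []
    meta: dict[str, str] = {}
    columns: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if columns is not None:
                sections.append((meta, columns, rows))
                meta, columns, rows = {}, None, []
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
            continue
        if columns is None:
            columns = [c.strip() for c in line.split(",")]
            continue
        rows.append((lineno, line.split(",")))
    if columns is not None:
        sections.append((meta, columns, rows))
    if not sections:
        raise InputError(f"{path}: no data sections found")
    return sections


def _require_meta(meta: dict[str, str], key: str, path: str) -> str:
    if key not in meta:
        raise InputError(
            f"{path}: missing required metadata header '# {key}=' (units are load-bearing)"
        )
    return meta[key]


def _check_monotone(time: np.ndarray, linenos: list[int], path: str, column: str) -> None:
    bad = np.nonzero(np.diff(time) <= 0)[0]
    if bad.size:
        raise InputError(
            f"{path}:{linenos[bad[0] + 1]}: non-monotone {column} value "
            f"{time[bad[0] + 1]!r} (must be strictly increasing)"
        )


# ---------------------------------------------------------------------------
# Trace series
# ---------------------------------------------------------------------------

def write_trace_series(series: TraceSeries, path: str | Path) -> None:
    path = Path(path)
    lines: list[str] = []
    for trace in series.traces:
        lines.append(f"# label={series.label}")
        lines.append(f"# receptor_uM={trace.receptor_conc_uM:.10g}")
        lines.append(f"# ligand_uM={trace.ligand_conc_uM:.10g}")
        lines.append(f"# n_averaged={trace.n_averaged}")
        lines.append("time_s,signal")
        for t, s in zip(trace.time_s, trace.signal):
            lines.append(f"{t:.10g},{s:.10g}")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")


def read_trace_series(path: str | Path) -> TraceSeries:
    path = Path(path)
    traces = []
    label = ""
    for meta, columns, rows in _split_sections(path):
        if columns[:2] != ["time_s", "signal"]:
            raise InputError(
                f"{path}: expected columns time_s,signal, got {columns}"
            )
        receptor = _parse_number(_require_meta(meta, "receptor_uM", str(path)), str(path), 0)
        ligand = _parse_number(_require_meta(meta, "ligand_uM", str(path)), str(path), 0)
        label = meta.get("label", label)
        linenos = [ln for ln, _ in rows]
        values = np.array(
            [[_parse_number(tok, str(path), ln) for tok in toks[:2]] for ln, toks in rows]
        )
        if values.size == 0:
            raise InputError(f"{path}: empty trace section (ligand_uM={ligand})")
        _check_monotone(values[:, 0], linenos, str(path), "time_s")
        traces.append(
            StoppedFlowTrace(
                time_s=values[:, 0], signal=values[:, 1],
                ligand_conc_uM=ligand, receptor_conc_uM=receptor,
                n_averaged=int(meta.get("n_averaged", 1)),
            )
        )
    return TraceSeries(traces=traces, label=label)


# ---------------------------------------------------------------------------
# Decay histograms
# ---------------------------------------------------------------------------

def write_decay_histogram(hist: DecayHistogram, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# channel_width_ns={hist.channel_width_ns:.10g}",
             f"# background={hist.background:.10g}"]
    has_irf = hist.irf is not None
    lines.append("time_ns,counts" + (",irf_counts" if has_irf else ""))
    for i, (t, c) in enumerate(zip(hist.channel_time_ns, hist.counts)):
        row = f"{t:.10g},{int(c)}"
        if has_irf:
            row += f",{hist.irf[i]:.10g}"
        lines.append(row)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_decay_histogram(path: str | Path) -> DecayHistogram:
    path = Path(path)
    meta, columns, rows = _split_sections(path)[0]
    if columns[:2] != ["time_ns", "counts"]:
        raise InputError(f"{path}: expected columns time_ns,counts, got {columns}")
    _require_meta(meta, "channel_width_ns", str(path))
    linenos = [ln for ln, _ in rows]
    values = np.array(
        [[_parse_number(tok, str(path), ln) for tok in toks] for ln, toks in rows]
    )
    _check_monotone(values[:, 0], linenos, str(path), "time_ns")
    irf = values[:, 2] if values.shape[1] > 2 else None
    return DecayHistogram(
        channel_time_ns=values[:, 0],
        counts=values[:, 1].astype(int),
        background=float(meta.get("background", 0.0)),
        irf=irf,
    )


# ---------------------------------------------------------------------------
# Titrations
# ---------------------------------------------------------------------------

def write_titration(curve: TitrationCurve, path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"# titrant={curve.titrant_label}",
        f"# titrant_unit={curve.titrant_unit}",
        f"# probe_nM={curve.probe_conc_nM:.10g}",
        f"# response_kind={curve.response_kind}",
        "titrant_conc,response",
    ]
    for x, y in zip(curve.titrant_conc, curve.response):
        lines.append(f"{x:.10g},{y:.10g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_titration(path: str | Path) -> TitrationCurve:
    path = Path(path)
    meta, columns, rows = _split_sections(path)[0]
    if columns[:2] != ["titrant_conc", "response"]:
        raise InputError(
            f"{path}: expected columns titrant_conc,response, got {columns}"
        )
    unit = _require_meta(meta, "titrant_unit", str(path))
    linenos = [ln for ln, _ in rows]
    values = np.array(
        [[_parse_number(tok, str(path), ln) for tok in toks[:2]] for ln, toks in rows]
    )
    _check_monotone(values[:, 0], linenos, str(path), "titrant_conc")
    return TitrationCurve(
        titrant_conc=values[:, 0], response=values[:, 1],
        probe_conc_nM=float(meta.get("probe_nM", 50.0)),
        titrant_label=meta.get("titrant", "RNA"),
        titrant_unit=unit,
        response_kind=meta.get("response_kind", "quench_fraction"),
    )


def read_trace_csv(path: str | Path):
    """Dispatch on the column header: trace series, decay histogram or titration."""
    path = Path(path)
    _, columns, _ = _split_sections(path)[0]
    head = columns[:2]
    if head == ["time_s", "signal"]:
        return read_trace_series(path)
    if head == ["time_ns", "counts"]:
        return read_decay_histogram(path)
    if head == ["titrant_conc", "response"]:
        return read_titration(path)
    raise InputError(f"{path}: unrecognized column header {columns}")


# ---------------------------------------------------------------------------
# Scheme and result serialization
# ---------------------------------------------------------------------------

def write_scheme(scheme: ReactionScheme, path: str | Path) -> None:
    Path(path).write_text(json.dumps(scheme.to_dict(), indent=2), encoding="utf-8")


def read_scheme(path: str | Path) -> ReactionScheme:
    return ReactionScheme.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_result_json(result: Any, path: str | Path, extra: dict | None = None) -> None:
    payload = _jsonable(result)
    if extra:
        payload = {**payload, **_jsonable(extra)}
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def format_pm(value: float, se: float, digits: int = 3) -> str:
    """``value±SE`` with the uncertainty rounded to one significant digit."""
    if not np.isfinite(value):
        return "n.d."
    if not np.isfinite(se) or se <= 0:
        return f"{value:.{digits}g}"
    exp = int(np.floor(np.log10(se)))
    se_r = round(se, -exp)
    decimals = max(-exp, 0)
    return f"{value:.{decimals}f}±{se_r:.{decimals}f}"


def render_decay_table(fits: dict[str, DecayFit]) -> str:
    """Lifetime table: per-component tau±SE with amplitude% in parentheses."""
    lines = ["sample\tcomponents (tau/ns (A/%))\tchi2_red"]
    for name, fit in fits.items():
        comps = "  ".join(
            f"{format_pm(c.tau_ns, c.tau_se)} ({format_pm(c.amplitude_pct, c.amplitude_se)})"
            for c in fit.components
        )
        lines.append(f"{name}\t{comps}\t{fit.reduced_chi2:.3f}")
    return "\n".join(lines)


def render_rate_table(fits: list[GlobalFitResult], table: ModelComparisonTable | None = None) -> str:
    """Rate-constant table in the conventional layout (value±SE per rate)."""
    from .kinetics import paper_symbol

    delta = {}
    if table is not None:
        delta = {r.scheme_id: (r.delta_aic, r.delta_bic) for r in table.rows}
    header = ["label", "scheme", "k1", "k-1", "k2", "k-2", "RMSD", "dAIC", "dBIC"]
    lines = ["\t".join(header)]
    for f in fits:
        cells = {paper_symbol(f.scheme_id, s): format_pm(v, f.rate_se.get(s, float("nan")))
                 for s, v in f.rates.items()}
        d_aic, d_bic = delta.get(f.scheme_id, (float("nan"), float("nan")))
        lines.append(
            "\t".join(
                [
                    f.label or "-",
                    f.scheme_id,
                    cells.get("k1", "—"),
                    cells.get("k-1", "—"),
                    cells.get("k2", "—"),
                    cells.get("k-2", "—"),
                    f"{f.rmsd:.6f}",
                    f"{d_aic:.0f}" if np.isfinite(d_aic) else "—",
                    f"{d_bic:.0f}" if np.isfinite(d_bic) else "—",
                ]
            )
        )
    return "\n".join(lines)


def render_kobs_table(result: PseudoFirstOrderResult) -> str:
    lines = ["ligand_uM\tk_obs_s"]
    for c, k in zip(result.ligand_concs_uM, result.k_obs):
        lines.append(f"{c:g}\t{k:.4g}")
    lines.append(
        f"k_on = {format_pm(result.k_on, result.k_on_se)} 1/(uM s), "
        f"intercept = {format_pm(result.intercept, result.intercept_se)} 1/s"
    )
    if result.excluded:
        lines.append(f"excluded saturating points (indices): {result.excluded}")
    return "\n".join(lines)


def render_hill_table(fits: dict[str, HillFit]) -> str:
    lines = ["sample\tK_D\th\tB_max"]
    for name, f in fits.items():
        lines.append(
            f"{name}\t{format_pm(f.kd, f.kd_se)} {f.titrant_unit}\t"
            f"{format_pm(f.h, f.h_se)}\t{format_pm(f.bmax, f.bmax_se)}"
        )
    return "\n".join(lines)
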