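"""Report rendering: delimited-text tables mirroring the publication layout.

Every output file embeds the config hash and seed in a comment header, so a
rendered table can always be traced to the run that produced it.  Values are
written as plain decimals by default; the German locale flag renders
``260.704.250,62 €`` style for table fidelity.
"""
from __future__ import annotations

from decimal import Decimal
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .bia import BudgetImpactResult
from .costing import ARMS, CATEGORIES, ComponentTable, split_direct_indirect_per_case
from .money import fmt_eur, parse_eur
from .sensitivity import SensitivityResult

HEADER_TEMPLATE = "# depotbia report | config={config_hash} seed={seed}\n"


def _fmt(value, locale: str) -> str:
    if isinstance(value, Decimal):
        return fmt_eur(value, locale=locale, symbol=False)
    return str(value)


def _write_table(frame: pd.DataFrame, path: Path, locale: str,
                 config_hash: str, seed: int) -> None:
    rendered = frame.copy()
    for col in rendered.columns:
        if rendered[col].map(lambda v: isinstance(v, Decimal)).any():
            rendered[col] = rendered[col].map(lambda v: _fmt(v, locale))
    with open(path, "w") as fh:
        fh.write(HEADER_TEMPLATE.format(config_hash=config_hash, seed=seed))
        rendered.to_csv(fh, index=False)


def read_table(path, locale: str = "en") -> pd.DataFrame:
    """Parse a rendered table back (euro columns as Decimal) — round-trip
    counterpart of the writer."""
    frame = pd.read_csv(path, comment="#", dtype=str)
    for col in frame.columns:
        if col.endswith("_eur") or col in ("oral", "depot"):
            frame[col] = frame[col].map(
                lambda v: parse_eur(v, locale) if isinstance(v, str) else v)
    return frame


def per_case_frame(table: ComponentTable) -> pd.DataFrame:
    rows = [{"category": c,
             "oral": table.per_case_eur("oral", c),
             "depot": table.per_case_eur("depot", c)} for c in CATEGORIES]
    rows.append({"category": "total",
                 "oral": table.per_case_total_eur("oral"),
                 "depot": table.per_case_total_eur("depot")})
    direct = {arm: split_direct_indirect_per_case(table, arm)[0] for arm in ARMS}
    rows.append({"category": "direct_costs",
                 "oral": direct["oral"], "depot": direct["depot"]})
    return pd.DataFrame(rows)


def sample_frame(table: ComponentTable) -> pd.DataFrame:
    rows = [{"category": c,
             "oral": table.sample_total_eur("oral", c),
             "depot": table.sample_total_eur("depot", c)} for c in CATEGORIES]
    rows.append({"category": "total",
                 "oral": table.sample_total_eur("oral"),
                 "depot": table.sample_total_eur("depot")})
    return pd.DataFrame(rows)


def population_frame(results: Sequence[BudgetImpactResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "scenario": r.scenario.label,
        "prevalence": r.scenario.prevalence,
        "market_share": r.scenario.market_share,
        "cost_oral_eur": r.cost_oral,
        "cost_depot_eur": r.cost_depot,
        "savings_eur": r.savings,
        "per_case_savings_eur": r.per_case_savings,
    } for r in results])


def sensitivity_frame(results: Sequence[SensitivityResult]) -> pd.DataFrame:
    """Sensitivity rows, base case first, then parameters in input order."""
    ordered = sorted(
        enumerate(results),
        key=lambda ir: (ir[1].direction != "base", ir[0]))
    rows = []
    for _, r in ordered:
        row = {"parameter": r.parameter, "direction": r.direction, "arm": r.arm,
               "per_case_eur": r.per_case_eur,
               "sample_total_eur": r.sample_total_eur}
        for label, value in r.population_eur.items():
            row[f"population[{label}]_eur"] = value
        rows.append(row)
    return pd.DataFrame(rows)


def render_report(bundle: Mapping[str, object], out_dir, *, locale: str = "en",
                  config_hash: str = "unknown", seed: int = 0) -> list[Path]:
    """Write every stage result in the bundle as a delimited-text table.

    Recognised bundle keys: ``component_table`` (per-case + sample tables),
    ``bia`` (list of BudgetImpactResult), ``market_share`` (DataFrame),
    ``sensitivity`` (list of SensitivityResult), ``endpoints`` (DataFrame),
    ``cohort_summary`` (DataFrame).  Raises on an empty bundle.
    """
    if not bundle:
        raise ValueError("nothing to render: the results bundle is empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = out / name
        _write_table(frame, path, locale, config_hash, seed)
        written.append(path)

    if "component_table" in bundle:
        table = bundle["component_table"]
        emit("per_case_costs.csv", per_case_frame(table))
        emit("sample_costs.csv", sample_frame(table))
    if "bia" in bundle:
        emit("population_costs.csv", population_frame(bundle["bia"]))
    if "market_share" in bundle:
        emit("market_share_costs.csv", bundle["market_share"])
    if "sensitivity" in bundle:
        emit("sensitivity.csv", sensitivity_frame(bundle["sensitivity"]))
    if "endpoints" in bundle:
        emit("endpoints.csv", bundle["endpoints"])
    if "cohort_summary" in bundle:
        emit("cohort_summary.csv",
             bundle["cohort_summary"].reset_index())
    if not written:
        raise ValueError(f"no renderable keys in bundle: {sorted(bundle)}")

    summary = out / "summary.txt"
    with open(summary, "w") as fh:
        fh.write(HEADER_TEMPLATE.format(config_hash=config_hash, seed=seed))
        fh.write("Rendered tables:\n")
        for p in written:
            fh.write(f"  - {p.name}\n")
        if "component_table" in bundle:
            table = bundle["component_table"]
            fh.write(
                f"Per-case totals: oral "
                f"{fmt_eur(table.per_case_total_eur('oral'), locale)} vs depot "
                f"{fmt_eur(table.per_case_total_eur('depot'), locale)} "
                f"(n={table.n})\n")
    written.append(summary)
    return written


def render_tornado(results: Sequence[SensitivityResult], path,
                   arm: str = "oral") -> Optional[Path]:
    """Optional tornado plot of per-case cost ranges for one arm."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    base = next((r.per_case_eur for r in results
                 if r.direction == "base" and r.arm == arm), None)
    spans: dict[str, list[Decimal]] = {}
    for r in results:
        if r.arm == arm and r.direction in ("min", "max"):
            spans.setdefault(r.parameter, []).append(r.per_case_eur)
    if base is None or not spans:
        return None
    names = sorted(spans, key=lambda n: max(spans[n]) - min(spans[n]))
    fig, ax = plt.subplots(figsize=(8, 0.5 * len(names) + 1.5))
    for i, name in enumerate(names):
        lo, hi = float(min(spans[name])), float(max(spans[name]))
        ax.barh(i, hi - lo, left=lo, color="#4878d0")
    ax.axvline(float(base), color="black", lw=1)
    ax.set_yticks(range(len(names)), names)
    ax.set_xlabel("per-case cost (€)")
    ax.set_title(f"One-way sensitivity, {arm} arm")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
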