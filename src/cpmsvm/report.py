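"""Assembling run results into JSON documents and plain-text summaries.

A report is regenerable from its JSON alone: the text renderer reads
nothing but the dictionary, so archiving the JSON preserves the full
result, and rendering twice gives byte-identical text.
"""

from __future__ import annotations

import numpy as np

from .consensus import NetworkCountMatrix
from .validation import CVOutcome, PermutationResult

__all__ = ["build_report", "render_text"]


def build_report(
    config: dict,
    outcomes: dict[str, CVOutcome],
    permutations: dict[str, PermutationResult] | None = None,
    sign_tests: dict[str, float] | None = None,
    search_tables: dict[str, dict[float, CVOutcome]] | None = None,
    network_counts: dict[str, NetworkCountMatrix] | None = None,
) -> dict:
    """Bundle outcomes keyed by run name (e.g. ``"both"``) into one document."""
    if not outcomes:
        raise ValueError("no outcomes to report")
    doc: dict = {"config": dict(config), "runs": {}}
    for name, out in outcomes.items():
        entry = out.to_dict()
        if permutations and name in permutations:
            entry["permutation"] = permutations[name].to_dict()
        if sign_tests and name in sign_tests:
            entry["sign_test_p"] = sign_tests[name]
        if search_tables and name in search_tables:
            entry["threshold_search"] = {
                str(t): {"accuracy": o.accuracy}
                for t, o in sorted(search_tables[name].items())
            }
        doc["runs"][name] = entry
    if network_counts:
        doc["network_counts"] = {
            name: {"labels": c.labels, "counts": c.counts.tolist()}
            for name, c in network_counts.items()
        }
    return doc


def _fmt_confusion(confusion: list[list[int]]) -> list[str]:
    c = np.asarray(confusion)
    return [
        "              pred=con  pred=scz",
        f"  true=con    {c[0, 0]:8d}  {c[0, 1]:8d}",
        f"  true=scz    {c[1, 0]:8d}  {c[1, 1]:8d}",
    ]


def render_text(doc: dict) -> str:
    """Deterministic plain-text summary of a report document."""
    lines = ["cpmsvm run report", "================="]
    cfg = doc.get("config", {})
    for key in sorted(cfg):
        lines.append(f"config {key} = {cfg[key]}")
    for name in sorted(doc.get("runs", {})):
        run = doc["runs"][name]
        lines.append("")
        lines.append(f"[{name}] mode={run['mode']} threshold={run['threshold']}")
        lines.append(f"  accuracy = {run['accuracy']:.4f} (n = {run['n']})")
        lines.extend(_fmt_confusion(run["confusion"]))
        if "permutation" in run:
            perm = run["permutation"]
            lines.append(
                f"  permutation p = {perm['p_value']:.6g} "
                f"(B = {perm['B']}, null mean = {perm['null_mean']:.4f})"
            )
        if "sign_test_p" in run:
            lines.append(f"  sign test p = {run['sign_test_p']:.6g}")
        if "threshold_search" in run:
            for t in sorted(run["threshold_search"], key=float):
                acc = run["threshold_search"][t]["accuracy"]
                lines.append(f"  search p<{t}: accuracy = {acc:.4f}")
    for name in sorted(doc.get("network_counts", {})):
        nc = doc["network_counts"][name]
        lines.append("")
        lines.append(f"network counts [{name}] (labels: {' '.join(nc['labels'])})")
        for row_label, row in zip(nc["labels"], nc["counts"]):
            lines.append(f"  {row_label:>4s} " + " ".join(f"{v:4d}" for v in row))
    return "\n".join(lines) + "\n"
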