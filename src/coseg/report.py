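"""Machine-readable results and the plain-text analysis report.

The JSON result file is the stable contract: identical inputs and settings
produce byte-identical output (no timestamps).  The text report renders the
same content for human review: a pedigree summary table, every validation
finding, the LR, and the ACMG/AMP evidence label when thresholds are
configured.  Nothing is transmitted or retained anywhere else.
"""

from __future__ import annotations

import json
from typing import Optional

from .pedigree import Finding, Pedigree
from .segregation import LrResult

__all__ = ["result_payload", "render_report", "write_outputs"]


def result_payload(result: LrResult, findings: list[Finding],
                   acmg_label: Optional[str] = None,
                   trimmed_ids: Optional[list[str]] = None) -> dict:
    """Assemble the machine-readable result dictionary."""
    return {
        "lr": result.lr,
        "log_numerator": result.log_numerator,
        "log_denominator": result.log_denominator,
        "n_configs": result.n_configs,
        "settings": result.settings,
        "acmg_evidence": acmg_label,
        "trimmed_individuals": sorted(trimmed_ids or []),
        "findings": [{"level": f.level, "code": f.code, "message": f.message,
                      "individual_id": f.individual_id} for f in findings],
        "per_individual": result.per_individual,
    }


def render_report(pedigree: Pedigree, payload: dict) -> str:
    """Plain-text report for local archiving."""
    s = payload["settings"]
    lines = [
        "Co-segregation analysis report",
        "==============================",
        "",
        f"Family:            {pedigree.family_id}",
        f"Gene:              {s['gene']}",
        f"Population:        {s['population']}",
        f"Multiple cancers:  {s['mode']}",
        f"CBC formulation:   {s['cbc']}",
        f"Allele frequency:  {s['allele_frequency']}",
        "",
        f"Likelihood ratio:  {payload['lr']:.4g}",
    ]
    if payload.get("acmg_evidence"):
        lines.append(f"ACMG evidence:     {payload['acmg_evidence']}")
    lines += ["",
              f"Genotype configurations consistent with observations: "
              f"{payload['n_configs']}"]
    if payload["trimmed_individuals"]:
        lines += ["", "Trimmed (young, unaffected, untested) individuals: "
                  + ", ".join(payload["trimmed_individuals"])]

    lines += ["", "Pedigree", "--------",
              f"{'id':<10}{'sex':<5}{'age':>6}  {'genotype':<12}{'proband':<9}cancers"]
    for m in pedigree.members.values():
        cancers = "; ".join(f"{e.cancer_type.value}@{e.age:g}" for e in m.events) or "-"
        lines.append(f"{m.id:<10}{m.sex.value:<5}{m.censor_age:>6g}  "
                     f"{m.genotype.value:<12}{'yes' if m.is_proband else '':<9}{cancers}")

    if payload["findings"]:
        lines += ["", "Validation findings", "-------------------"]
        for f in payload["findings"]:
            lines.append(f"[{f['level']}] {f['message']}")

    prov = payload.get("provenance")
    if prov:
        lines += ["", "Penetrance set provenance", "-------------------------", prov.rstrip()]
    return "\n".join(lines) + "\n"


def write_outputs(out_dir, pedigree: Pedigree, payload: dict) -> tuple[str, str]:
    """Write result.json and report.txt under ``out_dir``; returns the paths."""
    import os
    os.makedirs(out_dir, exist_ok=True)
    json_path = os.path.join(out_dir, "result.json")
    txt_path = os.path.join(out_dir, "report.txt")
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(txt_path, "w") as fh:
        fh.write(render_report(pedigree, payload))
    return json_path, txt_path
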