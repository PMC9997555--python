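"""Line-exclusion rules of the MA study.

Two filters, applied contamination-first:

1. *Contamination*: two MA lines grown on the same Petri dish that share
   an identical mutation call (same chromosome, position, ref and alt)
   almost certainly cross-contaminated; the line whose id carries an
   even trailing number is removed, once per dish, however many calls
   are shared.
2. *Depth*: lines whose mean sequencing coverage falls below a floor
   (30x by default) are removed — their calls are unreliable.

Both filters are idempotent and partition their input; mutations of a
removed line are excluded from every downstream count and exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

from .core import ConfigurationError, LineMetadata, MutationRecord


@dataclass
class QCReport:
    """Record of every removal and the rule that triggered it."""

    removals: List[dict] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"removals": list(self.removals), "warnings": list(self.warnings)}

    def to_log(self) -> str:
        lines = [
            f"REMOVED {r['line_id']} rule={r['rule']} detail={r['detail']}"
            for r in self.removals
        ]
        lines += [f"WARNING {w}" for w in self.warnings]
        return "\n".join(lines) if lines else "no removals"


def contamination_filter(
    mutations: Sequence[MutationRecord],
    lines: Sequence[LineMetadata],
) -> Tuple[List[LineMetadata], List[LineMetadata], QCReport]:
    """Remove the even-numbered dish-mate of every dish whose two lines
    share at least one identical mutation call."""
    report = QCReport()
    dishes: Dict[str, List[LineMetadata]] = {}
    for m in lines:
        dishes.setdefault(m.dish_id, []).append(m)
    for dish_id, members in dishes.items():
        if len(members) > 2:
            raise ConfigurationError(
                f"dish {dish_id} holds {len(members)} lines; the "
                "contamination rule is defined for dishes of at most two"
            )
    by_line: Dict[str, set] = {m.line_id: set() for m in lines}
    for rec in mutations:
        if rec.line_id in by_line:
            by_line[rec.line_id].add(rec.site_key)

    removed_ids = set()
    for dish_id, members in sorted(dishes.items()):
        if len(members) != 2:
            continue
        a, b = members
        shared = by_line[a.line_id] & by_line[b.line_id]
        if not shared:
            continue
        evens = [m for m in members if (m.numeric_suffix or 1) % 2 == 0]
        if not evens:
            report.warnings.append(
                f"dish {dish_id} shares {len(shared)} mutation(s) but no "
                "line has an even numeric suffix; nothing removed"
            )
            continue
        for m in evens:
            if m.line_id in removed_ids:
                continue
            removed_ids.add(m.line_id)
            site = sorted(shared)[0]
            report.removals.append(
                {
                    "line_id": m.line_id,
                    "rule": "contamination",
                    "detail": {
                        "dish_id": dish_id,
                        "n_shared": len(shared),
                        "shared_site": {
                            "chromosome": site[0],
                            "position": site[1],
                            "ref": site[2],
                            "alt": site[3],
                        },
                    },
                }
            )
    kept = [m for m in lines if m.line_id not in removed_ids]
    removed = [m for m in lines if m.line_id in removed_ids]
    return kept, removed, report


def depth_filter(
    lines: Sequence[LineMetadata], min_depth: float = 30.0
) -> Tuple[List[LineMetadata], List[LineMetadata], QCReport]:
    """Remove lines with mean coverage below ``min_depth``."""
    report = QCReport()
    kept, removed = [], []
    for m in lines:
        if m.mean_depth < min_depth:
            removed.append(m)
            report.removals.append(
                {
                    "line_id": m.line_id,
                    "rule": "depth",
                    "detail": {"mean_depth": m.mean_depth, "min_depth": min_depth},
                }
            )
        else:
            kept.append(m)
    return kept, removed, report


def apply_qc(
    mutations: Sequence[MutationRecord],
    lines: Sequence[LineMetadata],
    min_depth: float = 30.0,
) -> Tuple[List[LineMetadata], List[MutationRecord], QCReport]:
    """Contamination filter, then depth filter; returns the kept lines,
    the mutations belonging to them, and the merged report."""
    kept, _, rep1 = contamination_filter(mutations, lines)
    kept, _, rep2 = depth_filter(kept, min_depth=min_depth)
    report = QCReport(
        removals=rep1.removals + rep2.removals,
        warnings=rep1.warnings + rep2.warnings,
    )
    kept_ids = {m.line_id for m in kept}
    kept_mutations = [r for r in mutations if r.line_id in kept_ids]
    return kept, kept_mutations, report
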