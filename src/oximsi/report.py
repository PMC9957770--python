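"""Human-readable screen reports."""

from __future__ import annotations

import math

from .chem import AdductTarget


def render_report(calls, summary, targets: list[AdductTarget] | None = None) -> str:
    """Plain-text screen report: per-enzyme activity tables plus warnings."""
    lines = []
    by_enzyme: dict[str, list] = {}
    for c in calls:
        by_enzyme.setdefault(c.enzyme, []).append(c)

    for enzyme, ecalls in by_enzyme.items():
        s = summary.get(enzyme, {})
        lines.append(f"== Screen report: {enzyme} ==")
        lines.append(
            f"active donors: {s.get('n_active_donors', 0)}"
            f" ({', '.join(s.get('active_donors', [])) or 'none'})"
        )
        lines.append(
            f"active acceptors: {s.get('n_active_acceptors', 0)}"
            f" ({', '.join(s.get('active_acceptors', [])) or 'none'})"
        )
        lines.append("")
        lines.append(f"{'donor':>10} {'acceptor':>16} {'mean ratio':>11} "
                     f"{'+/- sd':>8} {'ctrl mean':>10} {'Z':>6}  call")
        for c in sorted(ecalls, key=lambda c: (c.acceptor, -(c.mean_ratio if not math.isnan(c.mean_ratio) else -1))):
            if not c.evaluable:
                mark = f"not evaluable ({c.reason})"
                lines.append(f"{c.donor:>10} {c.acceptor:>16} {'-':>11} {'-':>8} "
                             f"{c.control_mean:>10.4f} {'-':>6}  {mark}")
                continue
            mark = "* ACTIVE" if c.active else ""
            z = f"{c.z_factor:.2f}" if not math.isnan(c.z_factor) else "-"
            lines.append(
                f"{c.donor:>10} {c.acceptor:>16} {c.mean_ratio:>11.4f} "
                f"{c.ratio_sd:>8.4f} {c.control_mean:>10.4f} {z:>6}  {mark}"
            )
        lines.append("")

    if targets:
        warn_lines = []
        seen = set()
        for t in targets:
            for c in t.collisions:
                key = tuple(sorted((t.name, c.other.name)))
                if key in seen:
                    continue
                seen.add(key)
                kind = "degenerate pair" if c.degenerate else "m/z collision"
                warn_lines.append(
                    f"  {kind}: {t.name} / {c.other.name} (delta {c.delta_mz:.4f} Da)"
                )
            if not t.in_range:
                warn_lines.append(f"  out of instrument range: {t.name} ({t.conjugate_mz:.3f})")
        if warn_lines:
            lines.append("channel warnings:")
            lines.extend(warn_lines)
            lines.append("")
    return "\n".join(lines)
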