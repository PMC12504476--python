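"""Render PMC surfaces and the comparison radar chart.

Each policy's nine primary scores are arranged row-major into a 3x3
matrix and rendered as a bilinear-interpolated surface; depressions mark
weak dimensions, quantified as 1 - score in the concavity report.
"""

from pathlib import Path

from pmcindex import (
    builtin_score_table,
    concavity_report,
    evaluate_all,
    render_radar,
    render_surface,
    surface_matrix,
)

out = Path("pmc_figures")
table = builtin_score_table()
results = evaluate_all(table)

for r in results:
    matrix = surface_matrix(r.primary_scores)
    render_surface(matrix, out / f"surface_{r.policy}.png", factor=10)
    report = concavity_report(matrix)
    deepest = ", ".join(report.deepest)
    print(
        f"{r.policy}: deepest depression {report.max_depression:.2f} at {deepest} "
        f"(total shortfall {report.total_depression:.2f} of 9)"
    )

render_radar(results, out / "radar.png")
print(f"\nwrote {len(results)} surface plots and radar.png under {out}/")
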