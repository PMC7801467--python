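"""Figure helpers for report objects (optional; matplotlib Agg-safe).

These render the standard views of a compartment or laminar run: the
blob-centered heatmap with the mean-blob-diameter circle, the CO and
fluorescence radial profiles with their cubic fits, and pia-to-white-matter
laminar profiles with layer bands.
"""

from __future__ import annotations

import numpy as np


def plot_heatmap(hm, ax=None):
    """Render a blob-centered heatmap with the mean-blob-diameter circle."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    if ax is None:
        _, ax = plt.subplots()
    half = hm.side_um / 2
    ax.imshow(
        hm.grid,
        extent=(-half, half, -half, half),
        origin="upper",
        cmap="inferno" if hm.source == "fluorescence" else "gray",
    )
    if np.isfinite(hm.mean_blob_diameter_um):
        ax.add_patch(
            Circle((0, 0), hm.mean_blob_diameter_um / 2, fill=False,
                   edgecolor="k", linewidth=1.2)
        )
    ax.set_xlabel("µm from blob center")
    ax.set_title(f"{hm.source} heatmap (n={hm.n_blobs_used})")
    return ax


def plot_radial_profiles(report, ax=None):
    """CO (black) and fluorescence (blue) profiles with cubic fits."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.linspace(0, 1, 200)
    for prof, fit, color, label in (
        (report.co_profile, report.co_fit, "k", "CO"),
        (report.fluor_profile, report.fluor_fit, "tab:blue", "label"),
    ):
        ax.plot(prof.bin_centers, prof.bin_values, "o", color=color,
                markersize=3, label=label)
        ax.plot(x, fit.predict(x), "-", color=color, linewidth=1)
    ax.set_xlabel("normalized distance  B$_{ctr}$ (0) → I$_{ctr}$ (1)")
    ax.set_ylabel("normalized intensity")
    ax.set_ylim(0, 1.05)
    ax.legend(frameon=False)
    return ax


def plot_laminar_profiles(report, ax=None):
    """Per-case laminar profiles vs normalized cortical depth."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for case_id, prof in sorted(report.case_averages.items()):
        ax.plot(prof.bin_values, prof.depth_of_bin, label=case_id)
    ax.invert_yaxis()
    ax.set_xlabel("normalized label intensity")
    ax.set_ylabel("depth (pia = 0, white matter = 1)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def save_report_figures(report, out_dir) -> list:
    """Write the standard figures of a compartment report as PNGs."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    plot_heatmap(report.co_heatmap, axes[0])
    plot_heatmap(report.fluor_heatmap, axes[1])
    plot_radial_profiles(report, axes[2])
    fig.tight_layout()
    path = out / "compartment_report.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)
    return written
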