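"""End-to-end recipes: generate or load inputs, run one figure-style table.

Each recipe writes CSV tables plus a JSON manifest recording the inputs,
the full configuration and its hash, so re-running with the same config and
seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import synthetic
from .colocalization import puncta_association
from .config import RunConfig
from .encounters import behavior_fractions
from .granule_transport import domain_distribution, motion_fractions
from .growth_cone import classify_dynamics

RECIPES = ("mi", "fig2c", "fig6b", "fig6fgh", "filopodia", "coloc")


def run_recipe(name: str, config: RunConfig, out_dir: str | Path) -> Path:
    """Run one named recipe on generated fixtures; returns the table path."""
    if name not in RECIPES:
        raise ValueError(f"unknown recipe {name!r}; valid names: {', '.join(RECIPES)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    if name == "mi":
        from .synthetic import default_reference_line, make_tract_image
        from .tract_sorting import extract_profile, missorting_index, split_branches

        rows = []
        for f in [0.0, 0.1, 0.2, 0.3, 0.5, 1.0]:
            img, truth = make_tract_image(f, seed=seed)
            profile = extract_profile(img, default_reference_line(img))
            # faithful mode: the brachium boundary is known for the fixture
            split = split_branches(
                profile, manual_split=truth["midpoint_um"], dm_side=img.orientation
            )
            res = missorting_index(profile, split)
            rows.append((f, round(res.mean_Dm, 4), round(res.mean_Ds, 4), round(res.mi, 4)))
        table = pd.DataFrame(rows, columns=["missorted_fraction", "mean_Dm", "mean_Ds", "mi"])
    elif name == "fig6b":
        tracks, _ = synthetic.make_track_fixture("fig6b", seed=seed or 7)
        fr = motion_fractions(tracks, config.motion_threshold_um)
        table = pd.DataFrame(
            [(k.value, v) for k, v in fr.items()], columns=["motion_class", "percent"]
        )
    elif name == "fig2c":
        events, _ = synthetic.make_encounter("fig2c", seed=seed)
        table = behavior_fractions(events, config)
    elif name == "fig6fgh":
        frames = []
        for contact in ("none", "heterotypic", "homotypic"):
            counts, _ = synthetic.make_domain_timecourse(contact, seed=seed or 3)
            df = domain_distribution(counts)
            df.insert(0, "contact", contact)
            frames.append(df)
        table = pd.concat(frames, ignore_index=True)
    elif name == "filopodia":
        _, traces, _ = synthetic.make_gc_sequence(seed=seed or 5)
        s = classify_dynamics(traces, config.recording_s, config.filopodia_sampling_s,
                              config.filopodium_length_um)
        table = pd.DataFrame(
            [
                ("n_formation", s.n_formation),
                ("n_retraction", s.n_retraction),
                ("n_stable", s.n_stable),
                ("mean_lifetime_s", sum(s.lifetimes) / len(s.lifetimes) if s.lifetimes else None),
            ],
            columns=["metric", "value"],
        )
    else:  # coloc
        a, b, truth = synthetic.make_puncta_fixture(seed=seed or 13)
        frac = puncta_association(a, b, config.association_radius_um)
        table = pd.DataFrame(
            [("puncta_association", frac), ("n", truth["n"])], columns=["metric", "value"]
        )

    table_path = out / f"{name}.csv"
    with open(table_path, "w") as fh:
        fh.write(f"# axonquant recipe={name} config_hash={config.hash()}\n")
        table.to_csv(fh, index=False)
    manifest = {
        "recipe": name,
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "outputs": [table_path.name],
    }
    (out / f"{name}.manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return table_path
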