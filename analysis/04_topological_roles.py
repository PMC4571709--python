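#!/usr/bin/env python
"""Topological roles (z, PC) of every trophospecies in each regional web.

Summarizes z and PC over the annealing replicates stored by
03_modularity_null.py, classifies each species into the four role
regions, and writes one CSV per web under results/roles/.
"""

import argparse
import csv
import json

from _data import RESULTS, load_study, three_webs
from trophoweb import role_profiles
from trophoweb.modularity import ModulePartition, modularity_value


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    args = parser.parse_args()
    meta, region1, region2, newcomers, generalists, _ = load_study(args.seed)
    mod_file = RESULTS / "modularity.json"
    if not mod_file.exists():
        raise SystemExit("run 03_modularity_null.py first")
    modularity = json.loads(mod_file.read_text())

    out_dir = RESULTS / "roles"
    out_dir.mkdir(parents=True, exist_ok=True)
    for web in three_webs(meta, region1, region2, newcomers):
        stored = modularity[web.name]
        parts = [
            ModulePartition(
                assignment={k: int(v) for k, v in a.items()},
                M=modularity_value(web, {k: int(v) for k, v in a.items()}),
                I_s={}, d_s={},
            )
            for a in stored["replicate_assignments"]
        ]
        designated = ModulePartition(
            assignment={k: int(v) for k, v in stored["assignment"].items()},
            M=stored["M"], I_s={}, d_s={},
        )
        profiles = role_profiles(web, parts, designated)
        out = out_dir / f"{web.name}.csv"
        with out.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "module", "z_mean", "z_lo", "z_hi",
                             "pc_mean", "pc_lo", "pc_hi", "role", "degree"])
            for p in sorted(profiles, key=lambda p: -p.degree):
                writer.writerow([p.node, p.module, f"{p.z_mean:.4f}",
                                 f"{p.z_lo:.4f}", f"{p.z_hi:.4f}",
                                 f"{p.pc_mean:.4f}", f"{p.pc_lo:.4f}",
                                 f"{p.pc_hi:.4f}", p.role, p.degree])
        counts = {}
        for p in profiles:
            counts[p.role] = counts.get(p.role, 0) + 1
        print(f"{web.name}: {counts} -> {out.name}")
        present = [g for g in sorted(generalists) if g in web.nodes]
        if present:
            by_node = {p.node: p for p in profiles}
            for g in present:
                p = by_node[g]
                print(f"  super-generalist {g}: z={p.z_mean:.2f}, "
                      f"PC={p.pc_mean:.2f} -> {p.role}")


if __name__ == "__main__":
    main()
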