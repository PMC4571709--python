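#!/usr/bin/env python
"""Do modules segregate by habitat and trophic level?

Permutation discriminant test (habitat indicators + short-weighted trophic
level against module membership) for the regional webs, using the
designated partitions from 03_modularity_null.py. Writes
results/associations.json.
"""

import argparse
import json

from _data import RESULTS, load_study, three_webs
from trophoweb import module_trait_association, trophic_levels
from trophoweb.modularity import ModulePartition


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--nperm", type=int, default=999)
    args = parser.parse_args()
    meta, region1, region2, newcomers, _, _ = load_study(args.seed)
    mod_file = RESULTS / "modularity.json"
    if not mod_file.exists():
        raise SystemExit("run 03_modularity_null.py first")
    modularity = json.loads(mod_file.read_text())

    payload = {}
    for i, web in enumerate(three_webs(meta, region1, region2, newcomers)):
        part = ModulePartition(
            assignment={k: int(v) for k, v in modularity[web.name]["assignment"].items()},
            M=modularity[web.name]["M"], I_s={}, d_s={},
        )
        habitat = {n: web.habitat_of(n) for n in web.nodes}
        res = module_trait_association(
            part, habitat, trophic_levels(web),
            n_perm=args.nperm, seed=args.seed + 10 * i,
        )
        payload[web.name] = {
            "statistic": res.statistic,
            "p_value": res.p_value,
            "n_permutations": res.n_permutations,
            "per_module": res.per_module,
        }
        print(f"{web.name}: separation={res.statistic:.3f}, p={res.p_value:.4f}")
        for mod, comp in sorted(res.per_module.items()):
            frac = comp["habitat_fractions"]
            print(f"  module {mod} (n={comp['n']}): "
                  f"B={frac['B']:.2f} P={frac['P']:.2f} BP={frac['BP']:.2f}, "
                  f"mean SWTL={comp['mean_swtl']:.2f}")

    out = RESULTS / "associations.json"
    out.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
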