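# bronchoreach

How small must an endobronchial tool be to reach most lung lesions — and how
far must it travel "off-road" through parenchyma when it cannot stay inside
the airways?

Lung-cancer screening finds many small, peripheral lesions, and biopsy tools
(forceps, needles, ultrasound probes, bronchoscopes) can only advance down
an airway at least as wide as themselves.  `bronchoreach` answers the
reachability question in silico, for interventional-pulmonology and
device-design audiences:

1. grow a deterministic 3D airway tree (duct branching + space division,
   Murray-law diameters `d1³ + d2³ = d_parent³`, 3311 branches, trachea
   14.5 mm) inside a two-lobed ~6 L lung volume, at full inspiration and —
   by isotropic `capacity^(1/3)` scaling with capacity 0.35 — at expiration;
2. distribute spherical lesions from configurable spatial PDFs
   (peripheral- and upper-lobe-weighted, right lung favored; 3 replicate
   sets of 1000 lesions per phase);
3. for every lesion and lesion diameter 1–50 mm, find the airway diameters
   it touches; report, per tool size 1–9 mm, the **percent of reachable
   lesions** and the **off-road distance** `max(r2 − r1, 0)`, where `r1` is
   the lesion radius and `r2` the radius at which a growing concentric
   sphere first touches an airway at least as wide as the tool;
4. optionally overlay CT-measured lesion–airway tables (per-lesion diameter,
   contact-airway diameter, distances to the nearest 1/2/4/6 mm airways) on
   the simulated curves.

See `docs/methods.md` for the model, its assumptions, and its limitations.

## Worked example

```python
from bronchoreach import (GrowthConfig, make_lung_region, generate_tree,
                          tree_stats, default_nelson_pdfs, bounding_box,
                          sample_lesions, contact_profiles, percent_reachable,
                          summarize_offroad)

cfg = GrowthConfig()                      # 3311 branches, trachea 14.5 mm
region = make_lung_region(cfg)            # ~6 L two-lobed lung at inspiration
tree = generate_tree(cfg, region)         # deterministic: no randomness
print(tree_stats(tree)["main_bronchi_diameters_mm"])

lesions = sample_lesions(default_nelson_pdfs(), bounding_box(region),
                         n=1000, seed=1000, phase="inspiration")
profiles = contact_profiles(lesions.coords, tree)
table = percent_reachable(profiles)
print(table.at(1.0, 10.0))                # % of 10 mm lesions a 1 mm tool reaches
print(summarize_offroad(profiles, lesion_sizes=(10.0,), tool_grid=[1.0]))
```

Output (abridged):

```
[11.298986756852418, 11.710955011333246]
13.5
 mean_offroad_mm  sd_offroad_mm  n_reachable  n_unreachable
            7.15            6.3          666            334
```

Read: the two main bronchi come out at 11.3 and 11.7 mm; a 1 mm tool
confined to the airways reaches only 13.5% of 1 cm lesions in this
inspiration model; to reach the rest it would have to leave the airway and
cross on average 7.15 mm of parenchyma (SD 6.3 mm over the 666 lesions whose
growing sphere meets a ≥1 mm airway within the 25 mm search radius; the
other 334 — mostly lesions sampled in bounding-box corners outside the lung
— are counted separately as unreachable).  In the same model 992/1000
lesions of 1 mm diameter touch no airway at all, falling to 954/1000 at
5 mm: small peripheral lesions are overwhelmingly transbronchial targets.

## Command line

```sh
bronchoreach run-all --seed 1 --out results/study      # full study, all tables
bronchoreach generate-tree --out tree.csv              # branch table + morphometry
bronchoreach sample-lesions --seed 1 --out lesions/    # 6 lesion sets (CSV)
bronchoreach ct-compare --ct-table ct.csv --out overlay/
```

Outputs are long-format CSVs (phase, replicate, tool_mm, lesion_mm, value)
plus a JSON summary; every file carries a `config_hash` header line, and a
fixed seed + config reproduces them byte for byte.  Airway surfaces can be
exported as legacy ASCII VTK polydata with per-face local diameters (NaN
where the opposite wall could not be determined).

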