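# fluxtope

Exact characterization of the *optimal solution space* of flux balance
analysis (FBA) models: vertices, rays, linealities, flux modules,
elementary flux modes, and secondary objectives — all in rational
arithmetic, with no numerical tolerances.

## The problem

FBA finds a flux distribution **J** maximizing an objective
*Z* = **c**ᵀ**J** subject to steady state **N J** = 0 and bounds
**J**ᵐⁱⁿ ≤ **J** ≤ **J**ᵐᵃˣ.  The optimum *Z*\* is unique, but the optimal
flux distribution almost never is: the set of optimal **J** is a polyhedron
that can hold millions of corner points.  Every optimal flux decomposes as
a Minkowski sum

  **J**ᵒᵖᵗ = Σₖ αₖ **φ**ₖ + Σₖ βₖ **ρ**ₖ + Σₖ γₖ **ψ**ₖ,
  Σ αₖ = 1, α ≥ 0, β ≥ 0, γ free,

over vertices **φ**, extreme rays **ρ**, and linealities **ψ**.  The
combinatorial explosion of vertices comes from a handful of small
*flux modules* (subnetworks): disjoint reaction sets *A* whose internal
fluxes vary across optima while their net input–output stoichiometry
**N**_A **J**_A = **d** is fixed.  Enumerating each module's polytope
separately and multiplying the counts characterizes the whole space
without materializing the product.

The package is aimed at people analyzing alternate optima of
constraint-based metabolic models: it answers *which* metabolic routes are
optimal, how they relate to optimal-yield elementary flux modes (EFMs),
and which single route survives once a secondary objective — pathway
length *P_L* (number of active reactions), flux sum *P_J* = Σ|Jⱼ|, or
protein cost *P_C* = Σ cⱼ|Jⱼ| — is minimized over the optimum.

Splitting every reversible reaction into a forward/backward pair is a
first-class operation: it removes linealities, makes every
non-decomposable optimal route a vertex, and makes the secondary
objectives linear.

## Worked example

The package ships an 18-metabolite / 18-reaction toy network (boundary
source X, sink Y, an ATP/ADP cofactor loop, five reversible reactions)
with input capacity J₁ ≤ 2 and objective max J₁₈:

```console
$ fluxtope toy --out toy.txt
$ fluxtope enumerate toy.txt --no-split --out run_ns
optimum 1 | 4 vertices (5 enumerated over 2 subnetworks, 3 modules) | 0 rays | 1 linealities
$ fluxtope enumerate toy.txt --split --out run_s
optimum 1 | 12 vertices (7 enumerated over 3 subnetworks, 3 modules) | 7 rays | 0 linealities
```

Reading the output: the optimum *Z*\* = 1 is attained on a polyhedron
with 4 corner points while reversible reactions are intact — two
subnetworks with two alternative routes each (2×2), plus a reversible
cycle {R2–R4} that forms the single lineality.  After splitting, the
cycle subnetwork contributes alternatives of its own and a third
alternative route {R12, R15} becomes extreme, giving 2×2×3 = 12 vertices
(only 7 module vertices were actually enumerated) and 7 rays (one per
split pair plus the two orientations of the cycle).

```console
$ fluxtope efm toy.txt --out run_e
13 EFMs | 12 optimal-yield | 4 matched by vertices
$ fluxtope secondary toy.txt --split --objective P_L --out run_p
min P_L = 11 (attained by 1 of the enumerated vertices)
$ fluxtope secondary toy.txt --split --objective P_L --bound "R15=0,1/2" --out run_p2
min P_L = 12 (attained by 1 of the enumerated vertices)
```

Of the 13 EFMs, 12 produce Y at optimal yield; without splitting only a
third of them correspond to vertices, after splitting the correspondence
is one-to-one.  Minimizing pathway length collapses the 12-vertex
optimum to a single 11-reaction route; adding the second bound
J₁₅ ≤ ½ forces one more active reaction.

Every subcommand writes machine-readable reports (JSON summaries, TSV
tables of vertices/rays/linealities/EFMs with fluxes as exact `p/q`
strings) into the `--out` directory, byte-identically across reruns.

The same pipeline is available as a library:

```python
import fluxtope as ft
toy = ft.build_toy_model()
z = ft.solve_fba(toy).objective_value          # Fraction(1)
space = ft.build_optimal_space(toy, z)
ft.count_vertices(space)                        # (4, 5) = (product, sum)
```

Models load from the human-diffable tabular dialect shown in `toy.txt`
or from SBML Level 3 with the flux-bounds/objective (FBC) package
(`ft.read_model(path, format="sbml")`).

## Layout

| module | contents |
|---|---|
| `fluxtope.netmodel` | model types, toy fixture, random generator, splitting, tabular I/O |
| `fluxtope.sbml` | SBML L3/FBC reader and writer |
| `fluxtope.lp_core` | exact rational simplex, FBA, FVA, MILP wrapper |
| `fluxtope.modules_detect` | flux-module discovery, verification, submodel extraction |
| `fluxtope.polyhedra` | double description, vertices/rays/linealities, Minkowski membership |
| `fluxtope.efm` | EFM enumeration, optimal-yield filter, rank test, vertex matching |
| `fluxtope.objectives` | P_L / P_J / P_C, GPR cost vectors, secondary optimization |
| `fluxtope.cli_report` | `fluxtope` command-line interface and report writers |

See `docs/methods.md` for the algorithms, conventions, and limitations.
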