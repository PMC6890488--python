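# curveflow

An adaptive moving-mesh solver for **forced curve shortening flow** of
closed plane curves,

$$\mathcal{V} = \dot{\mathbf{x}}\cdot\mathbf{n} = \alpha(\mathbf{x},t)\,\kappa + \beta(\mathbf{x},t),$$

where $\kappa$ is the signed curvature, $\alpha \ge 0$ weights the
curvature-driven motion and $\beta$ is an external forcing. Flows of this
form drive the evolving interfaces of biological cell-membrane models,
geodesic active contours in image analysis, and grain boundaries in
materials — anywhere a sharp interface moves by curvature plus a force.

Tracking such a curve with marker particles that move purely in the normal
direction quickly ruins the mesh: nodes pile up where normals converge and
starve flat regions. `curveflow` adds a **tangential mesh velocity** derived
from a moving-mesh PDE: the nodes relax, at rate $1/\tau$, toward a
distribution that *equidistributes* a positive monitor function $M$ along
the curve ($M\,ds$ constant between neighbouring nodes),

$$\dot{\mathbf{x}}\cdot\mathbf{t} = \frac{P}{\tau\,(M|\mathbf{x}_\xi|)^{2}}\,\bigl(M|\mathbf{x}_\xi|\bigr)_\xi ,$$

with a spatial balancing operator $P$ ($P = 1$ or the more robust
$P = M|\mathbf{x}_\xi|^2$). Because the tangential velocity never changes
the curve's shape, mesh quality and solution accuracy can be controlled
independently of the geometric law. Supported monitors are uniform arc
length ($M = 1$) and a curvature-based monitor
$M = \tfrac12\bigl(M_{\mathrm{floor}} + |\kappa|^{1/2}\bigr)$ whose
adaptive floor (the mean of $|\kappa|^{1/2}$ over the curve) keeps flat
segments populated without any tuning parameter.

The discretization uses central finite differences on a periodic mesh of
`N` nodes and two implicit time integrators: backward Euler (**BE**,
first-order) and a Crank–Nicolson/backward Euler hybrid (**CNBE**,
second-order in the enclosed-area error). Each step solves a nonlinear
`2N × 2N` cyclic banded system by Picard iteration (linear solves are exact,
via a banded LU factorization with a rank-4 periodic correction). Capping
the Picard sweeps at 1 (BE) or 2 (CNBE) gives a semi-implicit mode that can
step across geometric singularities. Initial meshes are generated by an
iterated de Boor algorithm that equidistributes the chosen monitor over the
starting curve.

## Worked example

Shrink the ellipse $(3\cos 2\pi u, \sin 2\pi u)$ by classical curve
shortening flow ($\alpha = 1$, $\beta = 0$) with the curvature-based
monitor, the balanced operator $P = M|\mathbf{x}_\xi|^2$ and $\tau = 10$:

```python
import curveflow as cf

res = cf.run_named("ellipse", n_nodes=160, n_steps=1000, t_final=1.4,
                   scheme="CNBE", monitor="curvature", tau=10.0, p_mode="balanced")
rep = cf.area_error_l2(res)
pmax, pmin = cf.picard_stats(res)
print(f"final area A_h(T)  : {res.areas[-1]:.6f}")
print(f"exact A(0) - 2*pi*T: {res.areas[0] - 2*3.141592653589793*1.4:.6f}")
print(f"L2 area error      : {rep.l2_norm:.3e}")
print(f"Picard iterations  : max {pmax}, min {pmin}")
```

prints

```
final area A_h(T)  : 0.624921
exact A(0) - 2*pi*T: 0.625859
L2 area error      : 6.360e-04
Picard iterations  : max 4, min 3
```

The enclosed area of *any* closed curve under $\mathcal{V} = \kappa$
decreases at exactly $2\pi$ per unit time, so the third line is the exact
reference; the solver tracks it to $6\times10^{-4}$ with 160 nodes and at
most four Picard sweeps per step.

The same functionality is available from the shell:

```bash
curveflow init --curve ellipse --n 128 --monitor curvature --out mesh.csv
curveflow run --curve circle --n 512 --nt 200 --t 0.25 --scheme cnbe --out circle
curveflow converge --study circle-temporal --out studies/
curveflow picard-table --study ellipse-temporal --monitor curvature --tau 10
```

`curveflow run` writes `<prefix>_areas.csv` (per-step time, enclosed area
and Picard count) and `<prefix>_curve_<step>.csv` snapshots; options can
also be given in a YAML file via `--config` (explicit flags win).

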