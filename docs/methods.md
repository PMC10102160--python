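# Methods

## The model

All solvers in `graphtow` are built on one family of nonlocal operators on a
finite, simple, undirected weighted graph G = (V, E, w), w(x,y) > 0 on edges
and symmetric. For a vertex signal u the one-sided (upwind) weighted
differences are

    d_y^± u(x) = ( √w(x,y) · (u(y) − u(x)) )^± ,   a⁺ = max(a,0), a⁻ = max(−a,0),

with the L_p norms of the upwind gradient taken over the neighbourhood
I(x) = {y : w(x,y) > 0}. For p = ∞ this is the max of the clamped
differences; for finite p the clamped difference is raised to the power p
inside the sum. (The p → ∞ limit and the eikonal local solve both force the
exponent-p reading; a formulation without the inner exponent would not
reduce to the max form.)

From the gradients we form the three nonlocal morphological operators

    NLD(u)(x) = u(x) + ‖∇⁺u(x)‖∞        (dilation)
    NLE(u)(x) = u(x) − ‖∇⁻u(x)‖∞        (erosion)
    NLM(u)(x) = Σ_y w u(y) / Σ_y w       (weighted mean)

and their convex combination, the nonlocal average

    NLA(u) = (α/2) NLD(u) + (β/2) NLE(u) + γ NLM(u),   (α+β)/2 + γ = 1.

The operator Δ_{α,β,γ}u = NLA(u) − u reproduces the classical graph
operators at specific parameter points: (1,1,0) the ∞-Laplacian
½(‖∇⁺u‖∞ − ‖∇⁻u‖∞); (0,0,1) the mean (2-)Laplacian; α=β=(p−2)/p, γ=2/p the
game p-Laplacian. The triple is simultaneously the move law of a random-turn
Tug-of-War game: with probability α/2 the maximizing player moves the token,
β/2 the minimizing player, γ it jumps to a random neighbour drawn
proportionally to the edge weights.

One parameter point deserves a remark: the pure-erosion setting α=γ=0, β=1
(the eikonal regime) does not satisfy the simplex constraint — (0+1)/2 = ½ —
and gives Δ_{0,1,0} = −½‖∇⁻u‖∞, i.e. half of the eikonal operator.
`GameParameters` therefore enforces the constraint by default and admits the
off-simplex triple only with `validate=False`; the dictionary test asserts
the −½-proportional identity, which is what the algebra actually yields.
The eikonal equation itself is solved by the dedicated monotone solver, not
by this fixed point.

### Operator regime

Similarity weights (below) always lie in (0, 1]. Within that range NLD, NLE,
NLM and NLA are averaging operators: they fix constants, are positively
homogeneous (negative scales swap dilation and erosion, NLE(−u) = −NLD(u)),
commute with adding a constant, and are nondecreasing in every vertex value
— so the comparison and maximum principles and the convergence of the
fixed-point solver follow. Monotonicity with respect to the *centre* value
u(x) has derivative 1 − √w along the active edge, so it requires w ≤ 1;
with weights above 1 the dilation/erosion operators remain monotone in the
neighbour values but not in u(x). All builders in this package produce
weights in (0, 1], so the solvers always operate in the averaging regime.

## Graphs and weights

Edges carry similarity weights s(x,y) ∈ (0,1] in one of three forms:
constant 1, exponential exp(−d/σ²), or inverse 1/(d+1), where d is a
distance between vertex payloads (raw intensity, an n×n image patch in
row-major order with replicate padding, 3D coordinates, or a feature row;
images conventionally use the squared Euclidean patch distance). σ may be
given, per-vertex (geometric mean across an edge), or estimated globally as
the mean nonzero candidate distance. Weights below 10⁻¹² are pruned so
I(x) stays well defined.

Constructions: 4/8-adjacency pixel grids; k-NN graphs symmetrised by union
(mutual-k-NN available as an option — the union is the simplest undirected
completion of the directed k-NN relation); ε-ball graphs; region adjacency
graphs over a partition (region payload = member mean); and the k-NN
extension of a RAG by region means, which lets fronts reach non-adjacent
regions of similar colour. Vertices are 0-indexed; pixel (r, c) is vertex
r·W + c.

For inpainting, patch distances are computed over the positions known in
*both* patches (mean squared difference; weight 1 if no overlap), so the
weights never depend on values inside the hole.

## Interpolation (Dirichlet / parabolic)

The interpolation problem −Δ_{α,β,γ}u = h in A, u = g on ∂A is solved by the
damped explicit Euler iteration u ← u + Δt(NLA(u) − u + h), clamped to g on
∂A; Δt ∈ (0,1] keeps each step a convex combination (monotone and stable),
and Δt = 1 gives the plain averaging filter u ← NLA(u) + h used by
`solve_dirichlet`. Updates are synchronous (Jacobi-style). Convergence is
declared on the sup-norm update (default tol 10⁻⁶, max 10⁵ iterations); the
true residual ‖u − NLA(u) − h‖∞ on A is also reported, and non-convergence
is reported rather than raised. Channels of vector-valued signals are
processed independently with shared weights.

Initial guess: 0 on A for the bare solver; the applications warm-start at
the mean of the known data (`inpaint`: mean known pixel value, `colorize`:
mean scribble colour), which makes constant regions an exact fixed point at
the first step and shortens transients elsewhere. For images the whole
known set is used as ∂A (not just the hole's rim): same fixed point on A,
richer data. A spec is solvable iff every connected component containing
interior vertices also carries boundary data; this is validated up front.

## Eikonal solver and label propagation

The graph eikonal equation ‖∇⁻u‖_p = h with u fixed on seeds is solved by
label-setting (Dijkstra-like) front propagation. The local solve at x over
known neighbour values a_i with slownesses k_i = 1/√w and C = h(x) > 0 is

    p = ∞ :  x* = min_i (a_i + k_i C)
    p < ∞ :  Σ_i k_i^{−p} ((x* − a_i)⁺)^p = C^p,

the latter via the incremental Hopf–Lax scheme: activate neighbours in
ascending order of a_i until the candidate no longer exceeds the next value
(p = 1 linear, p = 2 the Osher–Sethian quadratic; p is restricted to
{1, 2, ∞}). Because the solution depends only on neighbours with a_i < x*,
settling vertices in nondecreasing value order reproduces the global fixed
point exactly — this monotone causality is asserted during every run.
Seeds may carry nonzero initial values (distance-to-reference maps);
unreachable vertices are reported as +∞ rather than an error, so
disconnected k-NN graphs degrade gracefully.

Multi-label propagation runs all fronts in one pass. The tentative value of
a vertex under label ℓ uses only settled neighbours carrying ℓ, so a front
stops where the domain ends or where another front arrived first. Ties are
deterministic: smaller label index, then smaller vertex index.

Applications: superpixels dilate a regular seed lattice (spacing s, offset
s/2) on a photometrically weighted 4-adjacency grid with h ≡ 1; every
region contains its seed and the region count equals the seed count.
Semi-supervised classification (`EikonalClassifier`, sklearn estimator API
with y = −1 for unlabelled samples) propagates class fronts over a k-NN
feature graph; prediction on new points takes the transduced label of the
nearest training sample.

## Tug-of-War engine

`value_iteration` computes the game value as the fixed point of the DPP
u = NLA(u) + h (interior), u = g (boundary) — by construction the same
fixed point as `solve_dirichlet`, which the tests pin to 10⁻⁹.
`simulate_game` plays the game forward: both players act greedily against a
value function (default: the value-iteration output), the running payoff h
accrues at interior visits, and the episode ends at the boundary with
payoff g. The random move samples neighbours proportionally to w so its
expectation is NLM — on weighted graphs this choice is forced by the DPP;
uniform sampling would only match for constant weights. Playouts are
advanced in lockstep as a vectorised batch, which is step-for-step
equivalent to independent episodes and keeps 2·10⁴ playouts per setting
well under a second. Episodes hitting the step cap (default 10⁵) are
counted and excluded from the mean. Exact MC/DPP agreement (within Monte
Carlo error) is claimed for unit-weight graphs, where the coin-flip move
rule coincides with the pairwise weight-dependent rule; for general
weights the simulator is exploratory and the DPP remains the ground truth.

## Synthetic data

The generators are pure functions of a `FixtureConfig` (seed mandatory,
bit-identical reruns):

- images 24×24 by default: a horizontal ramp, a two-tone vertical split
  (0.2 / 0.8), a sinusoidal texture, and a "holed" two-tone image with an
  8×8 masked square centred inside the left tone — so the inpainting task
  has a single-tone boundary and a known exact answer. Optional Gaussian
  noise, clipped to [0,1].
- feature blobs emulating a cytology-style morphology table: n = 400
  samples, d = 10 descriptors, c = 4 isotropic unit-variance Gaussian
  classes; random centroids rescaled so the minimum pairwise centroid
  distance is 6 within-class standard deviations. At d = 10 this is a
  moderately separated configuration (pairwise Bayes error well below 1%)
  of the size a desk-scale slide-classification experiment would use.
- point clouds: a unit plane patch and a radius-0.8 sphere at distance ≈ 6,
  two fixed colours, five scribbled vertices per primitive.

What the fixtures do *not* emulate: real textures and lighting, anisotropic
or heavy-tailed feature noise, class imbalance, label noise, or the scale
of real slide databases (thousands of cells, millions of pixels). Passing
tests demonstrate the solvers' mathematical correctness and end-to-end
behaviour at desk scale, not field performance on clinical or heritage
data.

## Numerical choices and limitations

- Solver tolerances: sup-norm update 10⁻⁶ (interpolation defaults),
  10⁻¹⁰–10⁻¹² where fixed points are compared across modules; eikonal
  causality slack 10⁻¹²; simplex constraint tolerance 10⁻¹⁰.
- The fixed-point iteration for α=β=1 (∞-Laplacian) converges linearly
  with a rate that degrades on long thin domains; problem sizes here
  (≤ ~10³ vertices per solve) keep runtimes in seconds. No multigrid or
  Gauss–Seidel acceleration is attempted.
- Image output quantizes to 8-bit PNG; round-trips through files are exact
  at 1/255 resolution, in-memory results are full precision.
- PLY support is ASCII x,y,z + red,green,blue vertex properties only;
  colours quantize to uint8 in the file. The whitespace XYZRGB text format
  round-trips at full precision.
- No directed graphs, no dynamic graph mutation during solves, no
  continuous-domain (mesh-free) operators, no GPU paths.
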