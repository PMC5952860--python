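"""Motion-grade quality control for multi-stack acquisitions.

Each joint scan is acquired in 3 axial stacks, each visually graded 1 (best)
to 5 (worst) for motion artifacts on both the scan and the re-scan. A stack
with grade > 3 on either scan is unusable; a joint is lost only when all of
its stacks are.
"""

from cortigap import StackGrades, apply_exclusions

grades = [
    StackGrades("MCP2-patient01", [1, 2, 1], [1, 1, 2]),  # clean pair
    StackGrades("MCP3-patient01", [4, 2, 1], [1, 5, 1]),  # two stacks lost
    StackGrades("MCP2-patient02", [4, 4, 5], [2, 1, 1]),  # all lost on scan 1
    StackGrades("MCP3-patient02", [1, 1, 4], [4, 1, 1]),  # same stack poor twice
]
res = apply_exclusions(grades, grade_max=3)

print(f"stacks excluded : {res.n_excluded_stacks} / {3 * len(grades)}")
for joint, stack in res.excluded_stacks:
    print(f"  {joint} stack {stack}")
print(f"joints excluded : {res.excluded_joints}")
print(f"joints analysed : {res.included_joints}")
print("A stack poor on both scans counts once; MCP2-patient02 is dropped")
print("entirely because no usable stack remains.")
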