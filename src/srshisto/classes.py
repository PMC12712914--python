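"""The fixed 8-class lung-tissue taxonomy shared by all modules."""

CLASS_NAMES = {
    0: "background",
    1: "normal alveoli",
    2: "immune cells",
    3: "low grade",
    4: "intermediate grade",
    5: "high grade",
    6: "stroma",
    7: "tracheal wall",
}

N_CLASSES = 8

#: tumor classes in grading order (lepidic, acinar/papillary, solid/micropapillary/CGP)
TUMOR_LOW, TUMOR_INTERMEDIATE, TUMOR_HIGH = 3, 4, 5
TUMOR_CLASSES = (TUMOR_LOW, TUMOR_INTERMEDIATE, TUMOR_HIGH)

#: default pixel scale of the imaging system (pixels per micron)
DEFAULT_PX_PER_UM = 2.8986
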