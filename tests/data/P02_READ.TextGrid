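File type = "ooTextFile"
Object class = "TextGrid"

xmin = 0.0
xmax = 2.0
tiers? <exists>
size = 1
item []:
    item [1]:
        class = "IntervalTier"
        name = "phones"
        xmin = 0.0
        xmax = 2.0
        intervals: size = 13
        intervals [1]:
            xmin = 0.3
            xmax = 0.35
            text = "P"
        intervals [2]:
            xmin = 0.35
            xmax = 0.5
            text = "EH1"
        intervals [3]:
            xmin = 0.5
            xmax = 0.56
            text = "K"
        intervals [4]:
            xmin = 0.56
            xmax = 0.7
            text = "AE1"
        intervals [5]:
            xmin = 0.7
            xmax = 0.74
            text = "B"
        intervals [6]:
            xmin = 0.74
            xmax = 0.82
            text = "AH0"
        intervals [7]:
            xmin = 1.02
            xmax = 1.07
            text = "T"
        intervals [8]:
            xmin = 1.07
            xmax = 1.2
            text = "IY1"
        intervals [9]:
            xmin = 1.25
            xmax = 1.29
            text = "D"
        intervals [10]:
            xmin = 1.29
            xmax = 1.45
            text = "AA1"
        intervals [11]:
            xmin = 1.45
            xmax = 1.5
            text = "P"
        intervals [12]:
            xmin = 1.5
            xmax = 1.56
            text = "R"
        intervals [13]:
            xmin = 1.56
            xmax = 1.7
            text = "UW1"
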