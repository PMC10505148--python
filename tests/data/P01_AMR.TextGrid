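File type = "ooTextFile"
Object class = "TextGrid"

xmin = 0.0
xmax = 4.0
tiers? <exists>
size = 2
item []:
    item [1]:
        class = "IntervalTier"
        name = "phones"
        xmin = 0.0
        xmax = 4.0
        intervals: size = 20
        intervals [1]:
            xmin = 0.5
            xmax = 0.54
            text = "P"
        intervals [2]:
            xmin = 0.54
            xmax = 0.64
            text = "AA1"
        intervals [3]:
            xmin = 0.7
            xmax = 0.75
            text = "P"
        intervals [4]:
            xmin = 0.75
            xmax = 0.85
            text = "AA1"
        intervals [5]:
            xmin = 0.9
            xmax = 0.96
            text = "P"
        intervals [6]:
            xmin = 0.96
            xmax = 1.06
            text = "AA1"
        intervals [7]:
            xmin = 1.1
            xmax = 1.15
            text = "P"
        intervals [8]:
            xmin = 1.15
            xmax = 1.27
            text = "AA1"
        intervals [9]:
            xmin = 1.3
            xmax = 1.34
            text = "P"
        intervals [10]:
            xmin = 1.34
            xmax = 1.5
            text = "AA1"
        intervals [11]:
            xmin = 2.5
            xmax = 2.55
            text = "T"
        intervals [12]:
            xmin = 2.55
            xmax = 2.66
            text = "AA1"
        intervals [13]:
            xmin = 2.71
            xmax = 2.76
            text = "T"
        intervals [14]:
            xmin = 2.76
            xmax = 2.86
            text = "AA1"
        intervals [15]:
            xmin = 2.9
            xmax = 2.96
            text = "T"
        intervals [16]:
            xmin = 2.96
            xmax = 3.08
            text = "AA1"
        intervals [17]:
            xmin = 3.13
            xmax = 3.17
            text = "T"
        intervals [18]:
            xmin = 3.17
            xmax = 3.27
            text = "AA1"
        intervals [19]:
            xmin = 3.31
            xmax = 3.36
            text = "T"
        intervals [20]:
            xmin = 3.36
            xmax = 3.49
            text = "AA1"
    item [2]:
        class = "IntervalTier"
        name = "trials"
        xmin = 0.0
        xmax = 4.0
        intervals: size = 2
        intervals [1]:
            xmin = 0.5
            xmax = 2.0
            text = "trial1"
        intervals [2]:
            xmin = 2.5
            xmax = 4.0
            text = "trial2"
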