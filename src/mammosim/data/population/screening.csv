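race,rural,frequency,probability
white,False,0,0.38
white,False,1,0.05
white,False,2,0.06
white,False,3,0.07
white,False,4,0.08
white,False,5,0.08
white,False,6,0.1
white,False,7,0.18
white,True,0,0.5
white,True,1,0.05
white,True,2,0.06
white,True,3,0.07
white,True,4,0.08
white,True,5,0.08
white,True,6,0.1
white,True,7,0.06
hispanic,False,0,0.5
hispanic,False,1,0.05
hispanic,False,2,0.06
hispanic,False,3,0.07
hispanic,False,4,0.08
hispanic,False,5,0.08
hispanic,False,6,0.1
hispanic,False,7,0.06
hispanic,True,0,0.579439
hispanic,True,1,0.046729
hispanic,True,2,0.056075
hispanic,True,3,0.065421
hispanic,True,4,0.074766
hispanic,True,5,0.074766
hispanic,True,6,0.093458
hispanic,True,7,0.009346
asian,False,0,0.45
asian,False,1,0.05
asian,False,2,0.06
asian,False,3,0.07
asian,False,4,0.08
asian,False,5,0.08
asian,False,6,0.1
asian,False,7,0.11
asian,True,0,0.558824
asian,True,1,0.04902
asian,True,2,0.058824
asian,True,3,0.068627
asian,True,4,0.078431
asian,True,5,0.078431
asian,True,6,0.098039
asian,True,7,0.009804
black,False,0,0.45
black,False,1,0.05
black,False,2,0.06
black,False,3,0.07
black,False,4,0.08
black,False,5,0.08
black,False,6,0.1
black,False,7,0.11
black,True,0,0.558824
black,True,1,0.04902
black,True,2,0.058824
black,True,3,0.068627
black,True,4,0.078431
black,True,5,0.078431
black,True,6,0.098039
black,True,7,0.009804
other,False,0,0.5
other,False,1,0.05
other,False,2,0.06
other,False,3,0.07
other,False,4,0.08
other,False,5,0.08
other,False,6,0.1
other,False,7,0.06
other,True,0,0.579439
other,True,1,0.046729
other,True,2,0.056075
other,True,3,0.065421
other,True,4,0.074766
other,True,5,0.074766
other,True,6,0.093458
other,True,7,0.009346
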