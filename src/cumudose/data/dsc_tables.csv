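structure,case,session,v_initial_cc,v_deformed_cc,v_intersection_cc,dsc_dir,dsc_rigid
HR-CTV,1,DIR1,25.4,29.9,25.4,0.79,0.70
HR-CTV,1,DIR2,25.4,20.5,16.4,0.71,0.49
HR-CTV,1,DIR3,25.4,20.0,16.6,0.73,0.57
HR-CTV,2,DIR1,17.8,20.6,15.3,0.80,0.35
HR-CTV,2,DIR2,17.8,18.0,13.4,0.75,0.69
HR-CTV,2,DIR3,17.8,18.1,13.4,0.75,0.14
HR-CTV,3,DIR1,40.0,48.7,36.5,0.82,0.25
HR-CTV,3,DIR2,40.0,32.8,26.8,0.73,0.46
HR-CTV,3,DIR3,40.0,33.7,27.7,0.75,0.30
HR-CTV,4,DIR1,18.1,21.4,16.5,0.83,0.66
HR-CTV,4,DIR2,18.1,13.1,10.9,0.70,0.48
HR-CTV,4,DIR3,18.1,17.6,12.5,0.70,0.42
HR-CTV,5,DIR1,27.5,24.0,20.8,0.85,0.47
HR-CTV,5,DIR2,27.5,27.5,21.8,0.83,0.53
HR-CTV,5,DIR3,27.5,24.8,21.7,0.88,0.43
rectum,1,DIR1,47.8,40.9,32.4,0.73,0.72
rectum,1,DIR2,47.8,26.9,24.6,0.74,0.66
rectum,1,DIR3,47.8,50.2,33.3,0.68,0.62
rectum,2,DIR1,46.6,54.1,42.5,0.85,0.74
rectum,2,DIR2,46.6,55.3,42.4,0.80,0.73
rectum,2,DIR3,46.6,48.1,40.7,0.75,0.67
rectum,3,DIR1,46.7,53.7,32.5,0.72,0.60
rectum,3,DIR2,46.7,47.0,29.6,0.71,0.70
rectum,3,DIR3,46.7,79.3,39.5,0.62,0.57
rectum,4,DIR1,95.4,59.9,56.7,0.76,0.52
rectum,4,DIR2,95.4,77.6,68.5,0.71,0.51
rectum,4,DIR3,95.4,75.7,69.0,0.84,0.41
rectum,5,DIR1,51.0,51.7,40.1,0.76,0.73
rectum,5,DIR2,51.0,36.9,31.4,0.74,0.50
rectum,5,DIR3,51.0,38.4,33.4,0.80,0.62
bladder,1,DIR1,191.2,237.9,178.2,0.86,0.83
bladder,1,DIR2,191.2,138.1,132.0,0.85,0.84
bladder,1,DIR3,191.2,276.4,177.7,0.88,0.82
bladder,2,DIR1,463.7,392.4,365.2,0.89,0.53
bladder,2,DIR2,463.7,434.6,121.0,0.92,0.54
bladder,2,DIR3,463.7,370.3,350.6,0.90,0.50
bladder,3,DIR1,231.7,411.3,223.6,0.89,0.79
bladder,3,DIR2,231.7,540.3,386.0,0.59,0.48
bladder,3,DIR3,231.7,213.9,229.4,0.93,0.82
bladder,4,DIR1,337.7,204.5,196.0,0.90,0.57
bladder,4,DIR2,337.7,184.7,171.5,0.91,0.60
bladder,4,DIR3,337.7,313.5,302.1,0.93,0.72
bladder,5,DIR1,155.9,143.0,134.2,0.89,0.77
bladder,5,DIR2,155.9,156.2,141.1,0.91,0.83
bladder,5,DIR3,155.9,207.9,148.8,0.80,0.70
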